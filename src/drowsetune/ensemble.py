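"""Weighted integration of the three classifiers, tuned by a genetic algorithm.

The integrated drowsy probability of a pattern is the convex combination

    LP = w1 * P_ann + w2 * P_svm + w3 * P_knn,   sum(w) = 1, w >= 0.

The weights are searched with a binary genetic algorithm: each weight is
encoded as a 16-bit field of a 48-bit chromosome, decoded as
``w_n = D_n / 2**16`` and renormalized to the simplex.  A chromosome's
fitness is ``1 / (dif + 1)`` where ``dif`` sums, over labelled training
patterns, the deviation of LP from its expected value (1 for drowsy
patterns, 0 for non-drowsy ones).  The GA runs fitness-proportional
(roulette) parent selection, single-point crossover, per-bit mutation and
full generational replacement with elitism, and returns the best weight
vector ever evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WeightVector",
    "GaConfig",
    "TrainingContext",
    "GaResult",
    "integrate_lp",
    "decode_chromosome",
    "encode_weights",
    "compute_dif",
    "fitness",
    "run_ga",
    "exhaustive_best_fitness",
    "classify_lp",
    "evaluate",
]


@dataclass(frozen=True)
class WeightVector:
    """Ensemble weights (w1, w2, w3) on the probability simplex."""

    w1: float
    w2: float
    w3: float

    def __post_init__(self) -> None:
        w = self.as_array()
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("weights must lie in [0, 1]")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3], dtype=float)


@dataclass
class GaConfig:
    """Genetic-algorithm parameters.

    ``bits_per_weight`` controls the chromosome resolution (16 bits per
    weight by default, 48 bits in total).
    """

    population_size: int = 50
    crossover_prob: float = 0.7
    mutation_prob: float = 0.001
    generations: int = 3000
    elitism: int = 1
    bits_per_weight: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2 or self.population_size % 2 != 0:
            raise ValueError("population size must be an even number >= 2")
        if not (0 <= self.crossover_prob <= 1 and 0 <= self.mutation_prob <= 1):
            raise ValueError("crossover/mutation probabilities must lie in [0, 1]")
        if self.elitism < 0 or self.elitism >= self.population_size:
            raise ValueError("elitism must be in [0, population_size)")
        if self.bits_per_weight < 1:
            raise ValueError("bits_per_weight must be positive")


@dataclass
class TrainingContext:
    """Per-pattern probability triples split by true label.

    ``set1`` holds (P1, P2, P3) rows for drowsy patterns (expected LP 1),
    ``set2`` for non-drowsy patterns (expected LP 0).
    """

    set1: np.ndarray
    set2: np.ndarray

    def __post_init__(self) -> None:
        self.set1 = np.atleast_2d(np.asarray(self.set1, dtype=float))
        self.set2 = np.atleast_2d(np.asarray(self.set2, dtype=float))
        for name, s in (("set1", self.set1), ("set2", self.set2)):
            if s.shape[0] == 0 or s.shape[1] != 3:
                raise ValueError(f"{name} must be a non-empty (m, 3) array")
            if np.any(s < 0) or np.any(s > 1):
                raise ValueError(f"{name} probabilities must lie in [0, 1]")

    @classmethod
    def from_probs(cls, probs: np.ndarray, labels: np.ndarray) -> "TrainingContext":
        probs = np.asarray(probs, dtype=float)
        labels = np.asarray(labels).astype(int).ravel()
        return cls(set1=probs[labels == 1], set2=probs[labels == 0])


@dataclass
class GaResult:
    weights: WeightVector
    best_fitness: float
    trace: np.ndarray = field(repr=False)  # per-generation best fitness
    mean_trace: np.ndarray = field(repr=False)
    best_chromosome: np.ndarray = field(repr=False)


def integrate_lp(p1, p2, p3, weights: WeightVector):
    """Integrated probability LP = w1*p1 + w2*p2 + w3*p3 (elementwise)."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    for p in (p1, p2, p3):
        if np.any(p < 0) or np.any(p > 1):
            raise ValueError("probabilities must lie in [0, 1]")
    lp = weights.w1 * p1 + weights.w2 * p2 + weights.w3 * p3
    return float(lp) if np.isscalar(p1) or lp.ndim == 0 else lp


def _decode_fields(bits: np.ndarray, bits_per_weight: int) -> np.ndarray:
    """Base-10 value of each of the three MSB-first bit fields."""
    powers = 2 ** np.arange(bits_per_weight - 1, -1, -1)
    return bits.reshape(3, bits_per_weight) @ powers


def decode_chromosome(bits, bits_per_weight: int = 16) -> WeightVector:
    """Decode a 3*bits_per_weight chromosome into simplex weights.

    Each field's base-10 value D_n maps to a raw weight D_n / 2**bits; the
    raw weights are renormalized so they sum to one.  A chromosome whose
    three fields are all zero carries no direction information and is
    rejected.
    """
    bits = np.asarray(bits).astype(int).ravel()
    if bits.size != 3 * bits_per_weight:
        raise ValueError(
            f"chromosome must have {3 * bits_per_weight} bits, got {bits.size}"
        )
    if np.any((bits != 0) & (bits != 1)):
        raise ValueError("chromosome bits must be 0 or 1")
    raw = _decode_fields(bits, bits_per_weight) / 2.0**bits_per_weight
    total = raw.sum()
    if total == 0:
        raise ValueError("all-zero chromosome decodes to no direction")
    w = raw / total
    return WeightVector(*w)


def encode_weights(weights: WeightVector, bits_per_weight: int = 16) -> np.ndarray:
    """Nearest chromosome for a weight vector (inverse of decoding, up to scale)."""
    scale = 2.0**bits_per_weight - 1
    fields = np.round(weights.as_array() * scale).astype(int)
    if fields.sum() == 0:
        fields[np.argmax(weights.as_array())] = 1
    bits = []
    for d in fields:
        bits.extend(int(b) for b in format(d, f"0{bits_per_weight}b"))
    return np.array(bits, dtype=int)


def compute_dif(ctx: TrainingContext, weights: WeightVector) -> float:
    """Summed deviation of LP from the expected labels.

    Drowsy patterns contribute 1 - LP, non-drowsy patterns contribute LP;
    a perfect ensemble reaches 0.
    """
    w = weights.as_array()
    lp1 = ctx.set1 @ w
    lp2 = ctx.set2 @ w
    return float(np.sum(1.0 - lp1) + np.sum(lp2))


def fitness(ctx: TrainingContext, weights: WeightVector) -> float:
    """GA fitness 1 / (dif + 1); equals 1 only for a perfect ensemble."""
    return 1.0 / (compute_dif(ctx, weights) + 1.0)


def _population_fitness(pop: np.ndarray, ctx: TrainingContext,
                        bits_per_weight: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized decode + fitness for a (S, L) bit population."""
    powers = 2 ** np.arange(bits_per_weight - 1, -1, -1)
    fields = pop.reshape(pop.shape[0], 3, bits_per_weight) @ powers
    raw = fields / 2.0**bits_per_weight
    w = raw / raw.sum(axis=1, keepdims=True)
    n1 = ctx.set1.shape[0]
    dif = n1 - w @ ctx.set1.sum(axis=0) + w @ ctx.set2.sum(axis=0)
    return 1.0 / (dif + 1.0), w


def _has_direction(pop: np.ndarray, bits_per_weight: int) -> np.ndarray:
    return pop.reshape(pop.shape[0], 3, bits_per_weight).any(axis=2).any(axis=1)


def run_ga(ctx: TrainingContext, cfg: GaConfig) -> GaResult:
    """Search the chromosome space for the weight vector minimizing dif.

    One run executes: random initialization (all-zero chromosomes redrawn),
    fitness evaluation, roulette parent selection, single-point crossover
    with probability ``crossover_prob`` at a uniform cut, per-bit mutation
    with probability ``mutation_prob`` (mutants losing all direction are
    redrawn), generational replacement, and elitism re-inserting the best
    chromosome found so far.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(cfg.seed)
    L = 3 * cfg.bits_per_weight
    S = cfg.population_size

    pop = rng.integers(0, 2, size=(S, L))
    bad = ~_has_direction(pop, cfg.bits_per_weight)
    while bad.any():
        pop[bad] = rng.integers(0, 2, size=(int(bad.sum()), L))
        bad = ~_has_direction(pop, cfg.bits_per_weight)

    best_fit = -np.inf
    best_chrom: np.ndarray | None = None
    trace = np.empty(cfg.generations)
    mean_trace = np.empty(cfg.generations)

    for gen in range(cfg.generations):
        fits, _ = _population_fitness(pop, ctx, cfg.bits_per_weight)
        gen_best = int(np.argmax(fits))
        if fits[gen_best] > best_fit:
            best_fit = float(fits[gen_best])
            best_chrom = pop[gen_best].copy()
        trace[gen] = best_fit
        mean_trace[gen] = float(fits.mean())
        if gen == cfg.generations - 1:
            break

        # roulette wheel over strictly positive fitness values
        probs = fits / fits.sum()
        parents = rng.choice(S, size=S, p=probs)
        new_pop = np.empty_like(pop)
        for i in range(0, S, 2):
            a = pop[parents[i]].copy()
            b = pop[parents[i + 1]].copy()
            if rng.random() < cfg.crossover_prob:
                cut = int(rng.integers(1, L))  # cut in [1, L-1]
                a[cut:], b[cut:] = b[cut:].copy(), a[cut:].copy()
            new_pop[i] = a
            new_pop[i + 1] = b
        # per-bit mutation; redraw mutants that lose all direction
        for i in range(S):
            while True:
                flips = rng.random(L) < cfg.mutation_prob
                cand = new_pop[i] ^ flips
                if _has_direction(cand[None, :], cfg.bits_per_weight)[0]:
                    new_pop[i] = cand
                    break
        if cfg.elitism > 0 and best_chrom is not None:
            new_pop[:1] = best_chrom
            if cfg.elitism > 1:
                order = np.argsort(fits)[::-1][: cfg.elitism - 1]
                new_pop[1 : cfg.elitism] = pop[order]
        pop = new_pop

    return GaResult(
        weights=decode_chromosome(best_chrom, cfg.bits_per_weight),
        best_fitness=best_fit,
        trace=trace,
        mean_trace=mean_trace,
        best_chromosome=best_chrom,
    )


def exhaustive_best_fitness(ctx: TrainingContext, bits_per_weight: int,
                            batch: int = 1 << 16) -> tuple[float, WeightVector]:
    """Best fitness over every decodable chromosome, by full enumeration.

    Feasible for small resolutions (6 bits per weight = 2**18 chromosomes);
    used as the ground-truth optimum when validating the GA.
    """
    n_field = 1 << bits_per_weight
    total = n_field**3
    best_fit = -np.inf
    best_fields: tuple[int, int, int] | None = None
    s1 = ctx.set1.sum(axis=0)
    s2 = ctx.set2.sum(axis=0)
    n1 = ctx.set1.shape[0]
    v = s2 - s1  # dif = n1 + w . v
    for start in range(0, total, batch):
        idx = np.arange(start, min(start + batch, total))
        d1, rem = np.divmod(idx, n_field * n_field)
        d2, d3 = np.divmod(rem, n_field)
        fields = np.stack([d1, d2, d3], axis=1).astype(float)
        tot = fields.sum(axis=1)
        ok = tot > 0
        w = fields[ok] / tot[ok, None]
        dif = n1 + w @ v
        fits = 1.0 / (dif + 1.0)
        j = int(np.argmax(fits))
        if fits[j] > best_fit:
            best_fit = float(fits[j])
            sel = idx[ok][j]
            d1v, remv = divmod(int(sel), n_field * n_field)
            best_fields = (d1v, *divmod(remv, n_field))
    raw = np.array(best_fields, dtype=float)
    w = raw / raw.sum()
    return best_fit, WeightVector(*w)


def classify_lp(lp: float, threshold: float = 0.5) -> int:
    """Decision rule: drowsy (1) iff LP >= threshold."""
    if not 0 <= threshold <= 1:
        raise ValueError("threshold must lie in [0, 1]")
    lp = np.asarray(lp, dtype=float)
    if np.any(lp < 0) or np.any(lp > 1):
        raise ValueError("LP must lie in [0, 1]")
    out = (lp >= threshold).astype(int)
    return int(out) if out.ndim == 0 else out


def evaluate(predictions, labels) -> dict[str, float]:
    """Correctness, false-positive and false-negative percentages.

    FN is the share of drowsy patterns classified non-drowsy (a missed
    alarm); FP is the share of non-drowsy patterns classified drowsy.
    """
    predictions = np.asarray(predictions).astype(int).ravel()
    labels = np.asarray(labels).astype(int).ravel()
    if predictions.size == 0:
        raise ValueError("cannot evaluate an empty prediction set")
    if predictions.size != labels.size:
        raise ValueError("predictions and labels must have equal length")
    correct = float(np.mean(predictions == labels) * 100.0)
    n_drowsy = int(np.sum(labels == 1))
    n_alert = int(np.sum(labels == 0))
    fn = (
        float(np.sum((labels == 1) & (predictions == 0)) / n_drowsy * 100.0)
        if n_drowsy
        else float("nan")
    )
    fp = (
        float(np.sum((labels == 0) & (predictions == 1)) / n_alert * 100.0)
        if n_alert
        else float("nan")
    )
    return {"correctness": correct, "fp": fp, "fn": fn}
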