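"""Model/Results front end for the drowsiness detector and refresh model.

:class:`DrowsinessDetector` is built from a labelled EEG trace; ``fit``
trains the three base classifiers, runs the genetic algorithm on their
training probabilities and returns a :class:`DetectorResults` carrying the
ensemble weights, the fitness trace and training diagnostics.

:class:`RefreshModel` is built from a user listening table; ``fit`` grows
the gain-ratio tree and returns a :class:`RefreshModelResults` that scores
songs and produces play schedules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import classifiers as clf_mod
from .classifiers import AnnClassifier, KnnClassifier, SvmClassifier
from .eeg import RawSignal, build_patterns, window_relative_energies
from .ensemble import (
    GaConfig,
    GaResult,
    TrainingContext,
    WeightVector,
    classify_lp,
    evaluate,
    run_ga,
)
from .music import FEATURE_COLUMNS
from .refresh import (
    RefreshTree,
    build_tree,
    pick_song,
    schedule_probs,
    score_music,
)

__all__ = [
    "DrowsinessDetector",
    "DetectorResults",
    "RefreshModel",
    "RefreshModelResults",
]

CLASSIFIER_NAMES = ("ann", "svm", "knn")


class DrowsinessDetector:
    """Drowsiness detection model over a labelled single-channel EEG trace.

    Parameters
    ----------
    signal : RawSignal
        The training trace (microvolts).
    labels : array-like of 0/1
        One label per non-overlapping window (1 = drowsy).
    T, stride : int
        Window length and hop in samples (default: non-overlapping
        1000-sample windows, i.e. 2 s at 500 Hz).
    pattern_lengths : (int, int, int)
        Windows per pattern for the ANN, SVM and kNN classifiers.  The
        defaults (3, 3, 4) are the empirically best lengths per
        classifier; the ensemble aligns the three views on the decision
        time (the pattern's last window) and drops the earliest windows
        where the longest pattern is undefined.
    """

    def __init__(
        self,
        signal: RawSignal,
        labels,
        T: int = 1000,
        stride: int | None = None,
        pattern_lengths: tuple[int, int, int] = (3, 3, 4),
    ):
        self.signal = signal
        self.T = T
        self.stride = stride
        self.pattern_lengths = tuple(pattern_lengths)
        self.re = window_relative_energies(signal, T=T, stride=stride)
        self.labels = np.asarray(labels).astype(int).ravel()
        if self.labels.size != self.re.shape[0]:
            raise ValueError(
                f"{self.re.shape[0]} windows but {self.labels.size} labels"
            )

    @classmethod
    def from_arrays(cls, samples, labels, fs: float = 500.0, **kwargs):
        return cls(RawSignal(samples=np.asarray(samples, float), fs=fs),
                   labels, **kwargs)

    # -- pattern bookkeeping -------------------------------------------------

    @property
    def warmup(self) -> int:
        """Windows before the first decision time (longest pattern - 1)."""
        return max(self.pattern_lengths) - 1

    def _aligned_patterns(self, re: np.ndarray, labels=None):
        """Per-classifier pattern views aligned on the decision time."""
        n_max = max(self.pattern_lengths)
        out = {}
        for name, n in zip(CLASSIFIER_NAMES, self.pattern_lengths):
            patterns, plabels = build_patterns(re, n, labels)
            out[name] = (patterns[n_max - n :],
                         None if plabels is None else plabels[n_max - n :])
        return out

    # -- estimation ----------------------------------------------------------

    def fit(
        self,
        ga_config: GaConfig | None = None,
        ann_kwargs: dict | None = None,
        svm_kwargs: dict | None = None,
        knn_k: int = 3,
        threshold: float = 0.5,
        seed: int = 0,
    ) -> "DetectorResults":
        """Train the three classifiers and GA-optimize the ensemble weights."""
        if ga_config is None:
            ga_config = GaConfig(population_size=50, generations=300, seed=seed)
        views = self._aligned_patterns(self.re, self.labels)
        aligned_labels = views["ann"][1]

        ann = AnnClassifier(seed=seed, **(ann_kwargs or {}))
        ann.fit(*views["ann"])
        svm = SvmClassifier(**(svm_kwargs or {}))
        svm.fit(*views["svm"])
        knn = KnnClassifier(k=knn_k)
        knn.fit(*views["knn"])
        fitted = {"ann": ann, "svm": svm, "knn": knn}

        probs = np.column_stack(
            [fitted[name].predict_proba(views[name][0]) for name in CLASSIFIER_NAMES]
        )
        ctx = TrainingContext.from_probs(probs, aligned_labels)
        ga = run_ga(ctx, ga_config)
        return DetectorResults(
            model=self,
            classifiers=fitted,
            weights=ga.weights,
            ga_result=ga,
            threshold=threshold,
            train_probs=probs,
            train_labels=aligned_labels,
        )


@dataclass
class DetectorResults:
    """Fitted detector: ensemble weights, classifiers and diagnostics."""

    model: DrowsinessDetector
    classifiers: dict
    weights: WeightVector
    ga_result: GaResult | None
    threshold: float
    train_probs: np.ndarray = field(repr=False)
    train_labels: np.ndarray = field(repr=False)

    # -- prediction ----------------------------------------------------------

    def _probs_for(self, signal: RawSignal | None = None,
                   re: np.ndarray | None = None) -> np.ndarray:
        m = self.model
        if re is None:
            re = m.re if signal is None else window_relative_energies(
                signal, T=m.T, stride=m.stride)
        views = {}
        n_max = max(m.pattern_lengths)
        for name, n in zip(CLASSIFIER_NAMES, m.pattern_lengths):
            patterns, _ = build_patterns(re, n)
            views[name] = patterns[n_max - n :]
        return np.column_stack(
            [self.classifiers[name].predict_proba(views[name])
             for name in CLASSIFIER_NAMES]
        )

    def predict_proba(self, signal: RawSignal | None = None,
                      re: np.ndarray | None = None) -> np.ndarray:
        """Integrated drowsy probability LP at each decision time.

        The first ``model.warmup`` windows of the trace have no value: the
        longest pattern is undefined there.
        """
        probs = self._probs_for(signal, re)
        return probs @ self.weights.as_array()

    def predict(self, signal: RawSignal | None = None,
                re: np.ndarray | None = None) -> np.ndarray:
        """0/1 drowsy decisions at each decision time."""
        return classify_lp(self.predict_proba(signal, re), self.threshold)

    def evaluate(self, signal: RawSignal | None = None,
                 re: np.ndarray | None = None,
                 labels=None) -> dict[str, float]:
        """Correctness / FP / FN percentages on a labelled trace."""
        if labels is None:
            labels = self.model.labels
        labels = np.asarray(labels).astype(int).ravel()[self.model.warmup :]
        return evaluate(self.predict(signal, re), labels)

    def component_evaluations(self, signal=None, re=None, labels=None) -> dict:
        """Per-classifier correctness/FP/FN at threshold 0.5."""
        probs = self._probs_for(signal, re)
        if labels is None:
            labels = self.model.labels
        labels = np.asarray(labels).astype(int).ravel()[self.model.warmup :]
        return {
            name: evaluate((probs[:, i] >= 0.5).astype(int), labels)
            for i, name in enumerate(CLASSIFIER_NAMES)
        }

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit report."""
        comps = {
            name: evaluate((self.train_probs[:, i] >= 0.5).astype(int),
                           self.train_labels)
            for i, name in enumerate(CLASSIFIER_NAMES)
        }
        ens = evaluate(
            classify_lp(self.train_probs @ self.weights.as_array(), self.threshold),
            self.train_labels,
        )
        lines = [
            "Drowsiness detector fit",
            "=" * 55,
            f"windows: {self.model.re.shape[0]}  "
            f"(drowsy {int(self.model.labels.sum())}, "
            f"alert {int((1 - self.model.labels).sum())})",
            f"pattern lengths (ann, svm, knn): {self.model.pattern_lengths}",
            f"decision threshold: {self.threshold}",
            "",
            "ensemble weights (GA):",
            f"  w1 (ann) = {self.weights.w1:.4f}",
            f"  w2 (svm) = {self.weights.w2:.4f}",
            f"  w3 (knn) = {self.weights.w3:.4f}",
        ]
        if self.ga_result is not None:
            lines.append(f"  best fitness = {self.ga_result.best_fitness:.6f}")
        lines += ["", "training-set performance (%):",
                  f"  {'classifier':<12}{'correct':>9}{'FP':>8}{'FN':>8}"]
        for name in CLASSIFIER_NAMES:
            e = comps[name]
            lines.append(
                f"  {name:<12}{e['correctness']:>9.1f}{e['fp']:>8.1f}{e['fn']:>8.1f}"
            )
        lines.append(
            f"  {'ensemble':<12}{ens['correctness']:>9.1f}{ens['fp']:>8.1f}{ens['fn']:>8.1f}"
        )
        return "\n".join(lines)

    def plot_fitness(self, ax=None):
        """Best/mean fitness per GA generation (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.ga_result.trace, label="best")
        ax.plot(self.ga_result.mean_trace, label="mean")
        ax.set_xlabel("generation")
        ax.set_ylabel("fitness 1/(dif+1)")
        ax.legend()
        return ax

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        payload = {
            "weights": list(self.weights.as_array()),
            "threshold": self.threshold,
            "T": self.model.T,
            "stride": self.model.stride,
            "pattern_lengths": list(self.model.pattern_lengths),
            "classifiers": {n: c.to_dict() for n, c in self.classifiers.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def load(path) -> "LoadedDetector":
        with open(path) as fh:
            d = json.load(fh)
        return LoadedDetector(
            weights=WeightVector(*d["weights"]),
            threshold=d["threshold"],
            T=d["T"],
            stride=d["stride"],
            pattern_lengths=tuple(d["pattern_lengths"]),
            classifiers={n: clf_mod.classifier_from_dict(c)
                         for n, c in d["classifiers"].items()},
        )


@dataclass
class LoadedDetector:
    """A deserialized detector usable for prediction only."""

    weights: WeightVector
    threshold: float
    T: int
    stride: int | None
    pattern_lengths: tuple[int, int, int]
    classifiers: dict

    @property
    def warmup(self) -> int:
        return max(self.pattern_lengths) - 1

    def predict_proba(self, signal: RawSignal) -> np.ndarray:
        re = window_relative_energies(signal, T=self.T, stride=self.stride)
        n_max = max(self.pattern_lengths)
        cols = []
        for name, n in zip(CLASSIFIER_NAMES, self.pattern_lengths):
            patterns, _ = build_patterns(re, n)
            cols.append(self.classifiers[name].predict_proba(patterns[n_max - n :]))
        return np.column_stack(cols) @ self.weights.as_array()

    def predict(self, signal: RawSignal) -> np.ndarray:
        return classify_lp(self.predict_proba(signal), self.threshold)


class RefreshModel:
    """Refreshing-music model over a user listening table.

    The table holds one row per song: music_id, F1..F6, refreshing
    (yes/no).  ``fit`` grows the gain-ratio decision tree.
    """

    def __init__(self, table: pd.DataFrame):
        missing = {"music_id", *FEATURE_COLUMNS, "refreshing"} - set(table.columns)
        if missing:
            raise ValueError(f"user table is missing columns: {sorted(missing)}")
        if table.empty:
            raise ValueError("user table must be non-empty")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "RefreshModel":
        return cls(pd.read_csv(path))

    def fit(self, max_height: int = 25, min_leaf: int = 1) -> "RefreshModelResults":
        tree = build_tree(self.table, max_height=max_height, min_leaf=min_leaf)
        return RefreshModelResults(model=self, tree=tree)


@dataclass
class RefreshModelResults:
    """Fitted refresh model: the tree plus scoring and scheduling."""

    model: RefreshModel
    tree: RefreshTree

    def score(self, features) -> float:
        """Refreshing score in [0, 1] for one feature vector."""
        return score_music(self.tree, features)

    def catalog_scores(self, catalog: pd.DataFrame) -> pd.Series:
        feats = catalog.set_index("music_id")[list(FEATURE_COLUMNS)]
        return pd.Series(
            {mid: self.score(row.to_numpy()) for mid, row in feats.iterrows()}
        )

    def schedule(self, catalog: pd.DataFrame) -> pd.Series:
        """Play probabilities over a catalog, proportional to scores."""
        return schedule_probs(self.catalog_scores(catalog))

    def recommend(self, catalog: pd.DataFrame, seed: int = 0):
        """Draw one song from the schedule."""
        return pick_song(self.schedule(catalog), seed=seed)

    def training_accuracy(self) -> float:
        labels = (self.model.table["refreshing"].astype(str).str.lower()
                  .map({"yes": 1, "no": 0}))
        feats = self.model.table[list(FEATURE_COLUMNS)].to_numpy(float)
        pred = np.array([self.score(x) >= 0.5 for x in feats], dtype=int)
        return float(np.mean(pred == labels.to_numpy()))

    def summary(self) -> str:
        t = self.tree
        return "\n".join([
            "Refreshing-music model fit",
            "=" * 40,
            f"records: {len(self.model.table)}",
            f"tree height: {t.height()} (limit {t.max_height})",
            f"leaves: {t.n_leaves()}",
            f"training accuracy (score >= 0.5): {self.training_accuracy():.3f}",
        ])
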