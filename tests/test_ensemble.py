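"""Weighted integration and the genetic-algorithm weight search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from drowsetune import (
    GaConfig,
    TrainingContext,
    WeightVector,
    classify_lp,
    compute_dif,
    decode_chromosome,
    evaluate,
    exhaustive_best_fitness,
    fitness,
    integrate_lp,
    run_ga,
)
from drowsetune.ensemble import encode_weights


def field_bits(d1, d2, d3, width=16):
    bits = []
    for d in (d1, d2, d3):
        bits.extend(int(b) for b in format(d, f"0{width}b"))
    return np.array(bits)


class TestIntegration:
    def test_projection_weight(self):
        w = WeightVector(1.0, 0.0, 0.0)
        assert integrate_lp(0.7, 0.1, 0.9, w) == pytest.approx(0.7)

    def test_convexity_fixes_constant(self):
        w = WeightVector(0.2, 0.5, 0.3)
        assert integrate_lp(0.4, 0.4, 0.4, w) == pytest.approx(0.4)

    def test_arithmetic_mean(self):
        w = WeightVector(1 / 3, 1 / 3, 1 / 3)
        assert integrate_lp(0.6, 0.9, 0.3, w) == pytest.approx(0.6)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            integrate_lp(1.2, 0.5, 0.5, WeightVector(1 / 3, 1 / 3, 1 / 3))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_in_each_probability(self, p_lo, p_hi):
        lo, hi = sorted((p_lo, p_hi))
        w = WeightVector(0.5, 0.3, 0.2)
        assert integrate_lp(lo, 0.4, 0.6, w) <= integrate_lp(hi, 0.4, 0.6, w) + 1e-12


class TestWeightVector:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError):
            WeightVector(0.5, 0.5, 0.5)

    def test_must_be_nonnegative(self):
        with pytest.raises(ValueError):
            WeightVector(-0.1, 0.6, 0.5)


class TestChromosomeDecoding:
    def test_equal_fields_give_uniform_weights(self):
        w = decode_chromosome(field_bits(32768, 32768, 32768))
        assert w.as_array() == pytest.approx([1 / 3, 1 / 3, 1 / 3])

    def test_single_nonzero_field(self):
        w = decode_chromosome(field_bits(65535, 0, 0))
        assert w.as_array() == pytest.approx([1.0, 0.0, 0.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            decode_chromosome(field_bits(0, 0, 0))

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="48"):
            decode_chromosome(np.ones(47, dtype=int))

    def test_reduced_width_decoding(self):
        w = decode_chromosome(field_bits(32, 32, 0, width=6), bits_per_weight=6)
        assert w.as_array() == pytest.approx([0.5, 0.5, 0.0])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 2**16 - 1), st.integers(0, 2**16 - 1),
           st.integers(0, 2**16 - 1))
    def test_decoded_weights_always_valid(self, d1, d2, d3):
        if d1 == d2 == d3 == 0:
            return
        w = decode_chromosome(field_bits(d1, d2, d3))
        arr = w.as_array()
        assert abs(arr.sum() - 1) < 1e-9
        assert np.all((arr >= 0) & (arr <= 1))

    def test_encode_decode_roundtrip(self):
        w = WeightVector(0.5, 0.25, 0.25)
        w2 = decode_chromosome(encode_weights(w))
        np.testing.assert_allclose(w2.as_array(), w.as_array(), atol=1e-4)


class TestDif:
    def test_worked_example(self):
        # drowsy LPs 0.6 and 0.8, non-drowsy LP 0.2:
        # |1-0.6| + |1-0.8| + |0-0.2| = 0.8
        ctx = TrainingContext(set1=[[0.6, 0.6, 0.6], [0.8, 0.8, 0.8]],
                              set2=[[0.2, 0.2, 0.2]])
        w = WeightVector(1 / 3, 1 / 3, 1 / 3)
        assert compute_dif(ctx, w) == pytest.approx(0.8)
        assert fitness(ctx, w) == pytest.approx(1 / 1.8)

    def test_perfect_ensemble_zero_dif(self):
        ctx = TrainingContext(set1=[[1, 1, 1]], set2=[[0, 0, 0]])
        w = WeightVector(0.3, 0.3, 0.4)
        assert compute_dif(ctx, w) == 0.0
        assert fitness(ctx, w) == 1.0

    def test_matches_per_pattern_loop_oracle(self, rng):
        probs = rng.random((10, 3))
        labels = rng.integers(0, 2, 10)
        labels[0], labels[1] = 1, 0
        ctx = TrainingContext.from_probs(probs, labels)
        w = WeightVector(0.2, 0.3, 0.5)
        expected = 0.0
        for p, lab in zip(probs, labels):
            lp = 0.2 * p[0] + 0.3 * p[1] + 0.5 * p[2]
            expected += (1 - lp) if lab == 1 else lp
        assert compute_dif(ctx, w) == pytest.approx(expected)

    def test_fitness_decreasing_in_dif(self):
        ctx_small = TrainingContext(set1=[[0.9, 0.9, 0.9]], set2=[[0.1, 0.1, 0.1]])
        ctx_big = TrainingContext(set1=[[0.6, 0.6, 0.6]], set2=[[0.4, 0.4, 0.4]])
        w = WeightVector(1 / 3, 1 / 3, 1 / 3)
        assert fitness(ctx_small, w) > fitness(ctx_big, w)


class TestGa:
    def make_informative_ctx(self, seed=0, n=40):
        rng = np.random.default_rng(seed)
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        probs = np.column_stack([
            labels.astype(float), np.full(n, 0.5), np.full(n, 0.5)
        ])
        return TrainingContext.from_probs(probs, labels)

    def test_recovers_informative_classifier(self):
        ctx = self.make_informative_ctx()
        res = run_ga(ctx, GaConfig(population_size=50, generations=200, seed=1))
        assert res.weights.w1 >= 0.9

    def test_recovery_across_seeds(self):
        ctx = self.make_informative_ctx()
        hits = 0
        for seed in range(10):
            res = run_ga(ctx, GaConfig(population_size=50, generations=200, seed=seed))
            hits += res.weights.w1 >= 0.9
        assert hits >= 9

    def test_same_seed_identical_trace(self):
        ctx = self.make_informative_ctx()
        cfg = GaConfig(population_size=20, generations=50, seed=9)
        a = run_ga(ctx, cfg)
        b = run_ga(ctx, cfg)
        np.testing.assert_array_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.best_chromosome, b.best_chromosome)

    def test_elitism_monotone_best_fitness(self):
        ctx = self.make_informative_ctx()
        res = run_ga(ctx, GaConfig(population_size=20, generations=80, seed=2))
        assert np.all(np.diff(res.trace) >= 0)

    def test_odd_population_rejected(self):
        with pytest.raises(ValueError):
            GaConfig(population_size=31)
        with pytest.raises(ValueError):
            GaConfig(population_size=0)

    def test_matches_exhaustive_on_reduced_chromosome(self, rng):
        probs = rng.random((10, 3))
        labels = rng.integers(0, 2, 10)
        labels[:2] = [0, 1]
        ctx = TrainingContext.from_probs(probs, labels)
        best, _ = exhaustive_best_fitness(ctx, bits_per_weight=6)
        res = run_ga(ctx, GaConfig(population_size=30, generations=100, seed=0,
                                   bits_per_weight=6, mutation_prob=1 / 18))
        assert best - res.best_fitness <= 1e-6
        assert res.best_fitness <= best + 1e-12  # GA cannot beat enumeration


class TestDecisionAndMetrics:
    @pytest.mark.parametrize("lp,expected", [(0.9, 1), (0.5, 1), (0.49, 0)])
    def test_threshold_rule(self, lp, expected):
        assert classify_lp(lp) == expected

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            classify_lp(0.5, threshold=1.5)

    def test_all_correct(self):
        m = evaluate([1, 0, 1], [1, 0, 1])
        assert m == {"correctness": 100.0, "fp": 0.0, "fn": 0.0}

    def test_one_missed_drowsy_of_three(self):
        m = evaluate([1, 1, 0, 0], [1, 1, 1, 0])
        assert m["fn"] == pytest.approx(100 / 3)
        assert m["fp"] == 0.0

    def test_matches_confusion_matrix_oracle(self, rng):
        pred = rng.integers(0, 2, 20)
        labels = rng.integers(0, 2, 20)
        labels[:2] = [0, 1]
        m = evaluate(pred, labels)
        tp = sum(1 for p, l in zip(pred, labels) if p == 1 and l == 1)
        tn = sum(1 for p, l in zip(pred, labels) if p == 0 and l == 0)
        fp = sum(1 for p, l in zip(pred, labels) if p == 1 and l == 0)
        fn = sum(1 for p, l in zip(pred, labels) if p == 0 and l == 1)
        assert m["correctness"] == pytest.approx(100 * (tp + tn) / 20)
        assert m["fp"] == pytest.approx(100 * fp / (fp + tn))
        assert m["fn"] == pytest.approx(100 * fn / (fn + tp))

    def test_empty_input_error(self):
        with pytest.raises(ValueError):
            evaluate([], [])
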