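"""Refreshing-music tree induction, scoring and probabilistic scheduling."""

import itertools

import numpy as np
import pandas as pd
import pytest

from drowsetune import (
    RefreshTree,
    build_tree,
    gen_user_table,
    pick_song,
    schedule_probs,
    score_music,
    update_user_table,
)
from drowsetune.refresh import (
    best_split,
    candidate_cut_points,
    class_entropy,
    gain_ratio,
    information_gain,
)


class TestCutPoints:
    @pytest.mark.parametrize(
        "values,expected",
        [([1, 3], [2.0]), ([5, 5, 5], []), ([1, 2, 4, 8], [1.5, 3.0, 6.0])],
    )
    def test_adjacent_midpoints(self, values, expected):
        np.testing.assert_allclose(candidate_cut_points(values), expected)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            candidate_cut_points([])


class TestEntropy:
    @pytest.mark.parametrize(
        "counts,expected", [((5, 5), 1.0), ((7, 0), 0.0), ((3, 1), 0.811278)]
    )
    def test_closed_forms(self, counts, expected):
        assert class_entropy(counts) == pytest.approx(expected, abs=1e-5)

    def test_empty_error(self):
        with pytest.raises(ValueError):
            class_entropy((0, 0))


class TestGain:
    def test_perfect_cut_gain_equals_parent_entropy(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([1, 1, 0, 0])
        assert information_gain(X, y, 0, 0.5) == pytest.approx(class_entropy((2, 2)))

    def test_uninformative_cut_zero_gain(self):
        X = np.array([[0.1], [0.1], [0.9], [0.9]])
        y = np.array([1, 0, 1, 0])
        assert information_gain(X, y, 0, 0.5) == pytest.approx(0.0)

    def test_matches_tally_oracle(self, rng):
        X = rng.random((8, 2))
        y = rng.integers(0, 2, 8)
        y[:2] = [0, 1]
        cut = float(np.median(X[:, 0]))
        got = information_gain(X, y, 0, cut)
        left = [lab for x, lab in zip(X[:, 0], y) if x <= cut]
        right = [lab for x, lab in zip(X[:, 0], y) if x > cut]
        if not left or not right:
            assert got == 0.0
            return
        def h(labels):
            c1 = sum(labels); c0 = len(labels) - c1
            return class_entropy((c1, c0))
        expected = h(list(y)) - (len(left) * h(left) + len(right) * h(right)) / 8
        assert got == pytest.approx(expected)

    def test_gain_ratio_closed_form(self):
        # before 1.0, after 0.5 -> (1 - 0.5) / 0.5 = 1.0
        # 8 records: left (4 pure), right (2,2) -> after = 0.5
        X = np.array([[0.0]] * 4 + [[1.0]] * 4)
        y = np.array([1, 1, 1, 1, 1, 1, 0, 0])
        assert gain_ratio(X, y, 0, 0.5) == pytest.approx(
            (class_entropy((6, 2)) - 0.5) / 0.5
        )

    def test_pure_children_infinite_ratio(self):
        X = np.array([[0.1], [0.2], [0.8], [0.9]])
        y = np.array([1, 1, 0, 0])
        assert gain_ratio(X, y, 0, 0.5) == float("inf")

    def test_zero_gain_split_zero_ratio(self):
        X = np.array([[0.1], [0.1], [0.9], [0.9]])
        y = np.array([1, 0, 1, 0])
        assert gain_ratio(X, y, 0, 0.5) == 0.0


class TestTree:
    def rule_table(self, n=40, seed=0):
        return gen_user_table(
            n, rule=lambda r: r["F4"] <= 0.7, seed=seed, ad_gap=(0.6, 0.8)
        )

    def test_recovers_planted_threshold_rule(self):
        table = self.rule_table()
        tree = build_tree(table)
        # depth-1 split on the average-duration feature
        assert not tree.root.is_leaf
        assert tree.root.feature == 3  # F4
        assert tree.root.left.is_leaf and tree.root.right.is_leaf
        X = table[["F1", "F2", "F3", "F4", "F5", "F6"]].to_numpy()
        y = (table["refreshing"] == "yes").astype(int).to_numpy()
        pred = np.array([score_music(tree, x) >= 0.5 for x in X], dtype=int)
        assert np.array_equal(pred, y)

    def test_all_refreshing_single_leaf(self):
        table = gen_user_table(10, rule=lambda r: True, seed=1)
        tree = build_tree(table)
        assert tree.root.is_leaf
        assert tree.root.score == 1.0

    def test_height_limit_one_gives_ratio_leaf(self):
        table = self.rule_table()
        tree = build_tree(table, max_height=1)
        assert tree.root.is_leaf
        refreshing = (table["refreshing"] == "yes").sum()
        assert tree.root.score == pytest.approx(refreshing / len(table))

    def test_height_never_exceeds_limit(self):
        table = gen_user_table(60, rule=lambda r: r["F1"] <= 65, noise_rate=0.2, seed=2)
        for limit in (2, 3, 5):
            assert build_tree(table, max_height=limit).height() <= limit

    def test_leaf_scores_equal_count_ratios(self):
        table = gen_user_table(50, rule=lambda r: r["F4"] <= 0.6, noise_rate=0.1, seed=3)
        tree = build_tree(table, max_height=4)

        def walk(node):
            if node.is_leaf:
                refreshing, total = node.counts
                assert 0 <= node.score <= 1
                assert node.score == refreshing / total
            else:
                walk(node.left)
                walk(node.right)

        walk(tree.root)

    def test_root_split_matches_exhaustive_argmax(self, rng):
        # tables of <= 8 records, 2 features: compare with full enumeration
        for seed in range(100):
            r = np.random.default_rng(seed)
            n = int(r.integers(3, 9))
            X = r.random((n, 2)).round(2)
            y = r.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            got = best_split(X, y)
            # exhaustive argmax with identical tie-break ordering
            best_key, best_pair = None, None
            for f in range(2):
                for cut in candidate_cut_points(X[:, f]):
                    ratio = gain_ratio(X, y, f, cut)
                    if ratio <= 0:
                        continue
                    key = (-ratio, -information_gain(X, y, f, cut), f, cut)
                    if best_key is None or key < best_key:
                        best_key, best_pair = key, (f, cut)
            assert got == best_pair

    def test_empty_table_error(self):
        with pytest.raises(ValueError):
            build_tree((np.empty((0, 2)), np.empty(0)))

    def test_json_roundtrip(self, tmp_path):
        table = self.rule_table()
        tree = build_tree(table)
        path = tmp_path / "tree.json"
        tree.to_json(path)
        loaded = RefreshTree.from_json(path)
        x = table[["F1", "F2", "F3", "F4", "F5", "F6"]].to_numpy()[0]
        assert score_music(loaded, x) == score_music(tree, x)
        assert loaded.max_height == tree.max_height


class TestScoring:
    def test_single_leaf_scores_everything(self):
        from drowsetune.refresh import TreeNode

        tree = RefreshTree(root=TreeNode(score=0.6, counts=(3, 5)))
        assert score_music(tree, np.zeros(6)) == 0.6
        assert score_music(tree, np.ones(6) * 99) == 0.6

    def test_missing_feature_error(self):
        table = gen_user_table(20, rule=lambda r: r["F4"] <= 0.7, seed=0,
                               ad_gap=(0.6, 0.8))
        tree = build_tree(table)
        with pytest.raises(ValueError, match="missing"):
            score_music(tree, [1.0, np.nan, 0.5, 0.4, 0.2, 0.1])


class TestScheduler:
    @pytest.mark.parametrize(
        "scores,expected",
        [
            ({"a": 0.6, "b": 0.4}, [0.6, 0.4]),
            ({"a": 2, "b": 2, "c": 2}, [1 / 3] * 3),
            ({"a": 0, "b": 0}, [0.5, 0.5]),
        ],
    )
    def test_normalization_and_fallback(self, scores, expected):
        probs = schedule_probs(scores)
        np.testing.assert_allclose(probs.to_numpy(), expected)

    def test_sum_to_one_large_catalog(self, rng):
        scores = dict(enumerate(rng.random(10_000)))
        assert abs(schedule_probs(scores).sum() - 1.0) < 1e-12

    def test_empty_catalog_error(self):
        with pytest.raises(ValueError):
            schedule_probs({})

    def test_negative_scores_rejected(self):
        with pytest.raises(ValueError):
            schedule_probs({"a": -0.1})

    def test_degenerate_schedule(self):
        probs = schedule_probs({"A": 1.0})
        assert pick_song(probs, seed=0) == "A"

    def test_same_seed_same_song(self):
        probs = schedule_probs({"a": 0.3, "b": 0.3, "c": 0.4})
        assert pick_song(probs, seed=42) == pick_song(probs, seed=42)

    def test_empirical_frequencies(self):
        probs = schedule_probs({"a": 0.6, "b": 0.4})
        rng = np.random.default_rng(5)
        draws = [pick_song(probs, seed=rng) for _ in range(20_000)]
        freq_a = draws.count("a") / len(draws)
        assert freq_a == pytest.approx(0.6, abs=0.02)


class TestUserTable:
    def make_table(self):
        return pd.DataFrame({
            "music_id": [5, 9],
            "F1": [82.0, 75.0], "F2": [0.9, 0.4], "F3": [0.5, 0.3],
            "F4": [1.3, 2.1], "F5": [0.4, 0.3], "F6": [0.3, 0.2],
            "refreshing": ["yes", "no"],
        })

    def test_new_song_appends(self):
        table = self.make_table()
        feats = {"F1": 64.0, "F2": 0.6, "F3": 0.1, "F4": 0.5, "F5": 0.2, "F6": 0.5}
        out = update_user_table(table, 13, "refreshed", features=feats)
        assert len(out) == 3
        assert out.loc[out["music_id"] == 13, "refreshing"].item() == "yes"

    def test_repeat_overwrites_label(self):
        table = self.make_table()
        out = update_user_table(table, 5, "not_refreshed")
        assert len(out) == 2
        assert out.loc[out["music_id"] == 5, "refreshing"].item() == "no"

    def test_unknown_id_without_features_error(self):
        with pytest.raises(KeyError):
            update_user_table(self.make_table(), 99, "refreshed")

    def test_invalid_outcome_error(self):
        with pytest.raises(ValueError):
            update_user_table(self.make_table(), 5, "meh")

    def test_label_flip_changes_leaf_score(self):
        table = gen_user_table(20, rule=lambda r: r["F4"] <= 0.7, seed=4,
                               ad_gap=(0.6, 0.8))
        tree = build_tree(table)
        target = table.iloc[0]
        flipped = update_user_table(
            table, target["music_id"],
            "not_refreshed" if target["refreshing"] == "yes" else "refreshed",
        )
        tree2 = build_tree(flipped, max_height=2)
        x = target[["F1", "F2", "F3", "F4", "F5", "F6"]].to_numpy(dtype=float)
        assert score_music(tree2, x) != score_music(tree, x)
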