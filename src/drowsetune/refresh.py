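"""Per-user refreshing-music model: gain-ratio decision tree + scheduler.

A user's listening history is a table of music feature vectors (F1..F6)
with a yes/no "refreshing" label.  A binary threshold tree is grown on the
continuous features: candidate cut points are midpoints of adjacent
distinct sorted values, splits are scored by a gain ratio whose denominator
is the post-split (size-weighted child) entropy, and leaves store the
fraction of refreshing pieces that reached them — the *refreshing score*
in [0, 1].

Note on the split criterion: the ratio divides the information gain by the
post-split class entropy, not by the split information of textbook C4.5.
A split with pure children therefore has an infinite ratio and beats any
impure split; ties are broken by larger gain, then lower feature index,
then lower cut value.

Scheduling turns per-song scores into play probabilities by simple
normalization, so a higher-scoring song is proportionally more likely to
be picked but no song monopolizes the stereo.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .music import FEATURE_COLUMNS

__all__ = [
    "TreeNode",
    "RefreshTree",
    "candidate_cut_points",
    "class_entropy",
    "information_gain",
    "gain_ratio",
    "best_split",
    "build_tree",
    "score_music",
    "schedule_probs",
    "pick_song",
    "update_user_table",
    "read_user_table",
]


@dataclass
class TreeNode:
    """Internal node (feature, cut) or leaf (score, counts).

    Records with ``feature <= K`` go left, the rest right.  A leaf's score
    is refreshing_count / total_count.
    """

    feature: int | None = None
    cut: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    score: float | None = None
    counts: tuple[int, int] | None = None  # (refreshing, total)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"score": self.score, "counts": list(self.counts)}
        return {
            "feature": self.feature,
            "cut": self.cut,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "score" in d:
            return cls(score=d["score"], counts=tuple(d["counts"]))
        return cls(
            feature=d["feature"],
            cut=d["cut"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass
class RefreshTree:
    """Binary threshold tree over F1..F6 with refreshing-score leaves."""

    root: TreeNode
    max_height: int = 25
    feature_names: tuple[str, ...] = FEATURE_COLUMNS

    def height(self) -> int:
        def h(node: TreeNode) -> int:
            if node.is_leaf:
                return 1
            return 1 + max(h(node.left), h(node.right))

        return h(self.root)

    def n_leaves(self) -> int:
        def count(node: TreeNode) -> int:
            if node.is_leaf:
                return 1
            return count(node.left) + count(node.right)

        return count(self.root)

    def to_json(self, path) -> None:
        payload = {
            "max_height": self.max_height,
            "feature_names": list(self.feature_names),
            "root": self.root.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "RefreshTree":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            root=TreeNode.from_dict(d["root"]),
            max_height=d["max_height"],
            feature_names=tuple(d["feature_names"]),
        )


def candidate_cut_points(values) -> np.ndarray:
    """Midpoints of adjacent distinct sorted values.

    A constant column yields no candidates.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot derive cut points from an empty value list")
    distinct = np.unique(values)
    return (distinct[:-1] + distinct[1:]) / 2.0


def class_entropy(counts) -> float:
    """Entropy (bits) of a class-count vector."""
    counts = np.asarray(list(counts), dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("entropy of an empty set is undefined")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def _counts(y: np.ndarray) -> tuple[int, int]:
    return int(np.sum(y == 1)), int(np.sum(y == 0))


def _post_split_entropy(y: np.ndarray, mask_left: np.ndarray) -> float:
    """Size-weighted entropy of the two children induced by a cut."""
    n = y.size
    nl = int(mask_left.sum())
    hl = class_entropy(_counts(y[mask_left])) if nl else 0.0
    hr = class_entropy(_counts(y[~mask_left])) if nl < n else 0.0
    return (nl * hl + (n - nl) * hr) / n


def information_gain(X: np.ndarray, y: np.ndarray, feature: int, cut: float) -> float:
    """Entropy before the cut minus the weighted entropy after it.

    A degenerate cut (one empty side) carries no information and scores 0.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    mask = X[:, feature] <= cut
    if mask.all() or not mask.any():
        return 0.0
    return class_entropy(_counts(y)) - _post_split_entropy(y, mask)


def gain_ratio(X: np.ndarray, y: np.ndarray, feature: int, cut: float) -> float:
    """(entropy before - entropy after) / entropy after.

    Pure children make the denominator zero: the ratio is +inf and such a
    split wins any comparison.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    mask = X[:, feature] <= cut
    if mask.all() or not mask.any():
        return 0.0
    before = class_entropy(_counts(y))
    after = _post_split_entropy(y, mask)
    gain = before - after
    if after == 0.0:
        return float("inf") if gain > 0 else 0.0
    return gain / after


def best_split(X: np.ndarray, y: np.ndarray) -> tuple[int, float] | None:
    """Best (feature, cut) by gain ratio over all candidate cut points.

    Ties are broken by larger information gain, then lower feature index,
    then lower cut value.  Returns None when no cut has positive gain.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y).astype(int).ravel()
    best: tuple[float, float, int, float] | None = None  # (-ratio,-gain,f,cut) ordering
    for f in range(X.shape[1]):
        for cut in candidate_cut_points(X[:, f]):
            ratio = gain_ratio(X, y, f, cut)
            if ratio <= 0:
                continue
            gain = information_gain(X, y, f, cut)
            key = (-ratio, -gain, f, cut)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[2], best[3]


def build_tree(records, max_height: int = 25, min_leaf: int = 1,
               feature_names: tuple[str, ...] = FEATURE_COLUMNS) -> RefreshTree:
    """Grow the refreshing-music tree by recursive gain-ratio splitting.

    Parameters
    ----------
    records : DataFrame with F1..F6 + ``refreshing`` columns, or (X, y) pair
        The user's listening table; ``refreshing`` may be yes/no strings or
        0/1 integers.
    max_height : int
        Level limit counting the root as level 1; a node at the limit
        becomes a leaf (over-fitting guard).
    min_leaf : int
        Minimum records on each side of an accepted split.

    Splitting stops on purity, at the height limit, when no candidate cut
    has positive gain, or when a split would starve a child below
    ``min_leaf``.
    """
    X, y = _records_to_xy(records, feature_names)
    if X.shape[0] == 0:
        raise ValueError("cannot build a tree from an empty table")
    if max_height < 1:
        raise ValueError("max_height must be at least 1")

    def make_leaf(yv: np.ndarray) -> TreeNode:
        refreshing = int(np.sum(yv == 1))
        total = int(yv.size)
        return TreeNode(score=refreshing / total, counts=(refreshing, total))

    def grow(Xv: np.ndarray, yv: np.ndarray, level: int) -> TreeNode:
        if level >= max_height or np.all(yv == yv[0]):
            return make_leaf(yv)
        split = best_split(Xv, yv)
        if split is None:
            return make_leaf(yv)
        f, cut = split
        mask = Xv[:, f] <= cut
        if mask.sum() < min_leaf or (~mask).sum() < min_leaf:
            return make_leaf(yv)
        return TreeNode(
            feature=f,
            cut=float(cut),
            left=grow(Xv[mask], yv[mask], level + 1),
            right=grow(Xv[~mask], yv[~mask], level + 1),
        )

    return RefreshTree(root=grow(X, y, 1), max_height=max_height,
                       feature_names=tuple(feature_names))


def _records_to_xy(records, feature_names) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, tuple):
        X, y = records
        return (np.atleast_2d(np.asarray(X, dtype=float)),
                np.asarray(y).astype(int).ravel())
    df = records
    X = df[list(feature_names)].to_numpy(dtype=float)
    y = _labels_to_int(df["refreshing"])
    return X, y


def _labels_to_int(col) -> np.ndarray:
    vals = pd.Series(col)
    if vals.dtype == object:
        mapped = vals.str.strip().str.lower().map({"yes": 1, "no": 0})
        if mapped.isna().any():
            raise ValueError("refreshing labels must be yes/no or 0/1")
        return mapped.to_numpy(dtype=int)
    return vals.to_numpy(dtype=int)


def score_music(tree: RefreshTree, features) -> float:
    """Route a feature vector to a leaf and return its refreshing score."""
    if hasattr(features, "as_array"):
        features = features.as_array()
    x = np.asarray(features, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("feature vector contains missing values")
    node = tree.root
    while not node.is_leaf:
        if node.feature >= x.size:
            raise ValueError(
                f"feature vector has {x.size} values but the tree tests "
                f"feature index {node.feature}"
            )
        node = node.left if x[node.feature] <= node.cut else node.right
    return float(node.score)


def schedule_probs(scores) -> pd.Series:
    """Per-song play probabilities proportional to refreshing scores.

    ``scores`` maps music_id -> score (dict or Series).  An all-zero score
    table falls back to the uniform distribution.
    """
    s = pd.Series(scores, dtype=float)
    if s.empty:
        raise ValueError("cannot schedule an empty catalog")
    if (s < 0).any():
        raise ValueError("scores must be non-negative")
    total = s.sum()
    if total == 0:
        return pd.Series(1.0 / len(s), index=s.index)
    return s / total


def pick_song(schedule: pd.Series, seed: int | np.random.Generator = 0):
    """One categorical draw from the play schedule; seeded, reproducible."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(schedule), p=schedule.to_numpy())
    return schedule.index[idx]


def update_user_table(table: pd.DataFrame, music_id, outcome: str,
                      features=None) -> pd.DataFrame:
    """Record a play outcome; the latest label for a song wins.

    ``outcome`` is ``"refreshed"`` or ``"not_refreshed"``.  A song not yet
    in the table needs its feature vector (from the catalog) to be
    appended; without features an unknown id is an error.  Returns a new
    table; the input is not mutated.
    """
    if outcome not in ("refreshed", "not_refreshed"):
        raise ValueError("outcome must be 'refreshed' or 'not_refreshed'")
    label = "yes" if outcome == "refreshed" else "no"
    table = table.copy()
    present = table["music_id"] == music_id
    if present.any():
        table.loc[present, "refreshing"] = label
        return table
    if features is None:
        raise KeyError(f"music id {music_id!r} not in table and no features given")
    if hasattr(features, "as_dict"):
        features = features.as_dict()
    row = {"music_id": music_id, **features, "refreshing": label}
    if table.empty:
        return pd.DataFrame([row], columns=table.columns if len(table.columns) else None)
    return pd.concat([table, pd.DataFrame([row])], ignore_index=True)


def read_user_table(path) -> pd.DataFrame:
    """Read a music_id,F1..F6,refreshing CSV table."""
    df = pd.read_csv(path)
    missing = {"music_id", *FEATURE_COLUMNS, "refreshing"} - set(df.columns)
    if missing:
        raise ValueError(f"user table is missing columns: {sorted(missing)}")
    return df
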