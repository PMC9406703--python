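"""Random Forest classifier, written from first principles.

Bagging (bootstrap resamples of the training set), uniform random feature
subsets at every split, exhaustive threshold search at midpoints between
consecutive distinct feature values, and Gini impurity decrease as the split
criterion — the classical ensemble, binary-class form, with a fixed class
order (odontogenic first) and deterministic behaviour under a fixed seed.

This module is deliberately self-contained: the ensemble is the pipeline's
diagnostic stage and its split/vote mechanics are part of what the package
tests, so no external learning library stands behind it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError, FitError, ShapeError
from .scene_sim import NON_ODONTOGENIC, ODONTOGENIC

_TIE_TOL = 1e-12

#: Class order everywhere in this module: index 0 = odontogenic (the majority
#: class, which also receives tie votes), index 1 = non-odontogenic.
CLASS_ORDER: tuple[str, str] = (ODONTOGENIC, NON_ODONTOGENIC)


def gini(counts: Sequence[int]) -> float:
    """Gini impurity 1 - sum((n_c/n)^2); in [0, 0.5] for two classes."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise DegenerateInputError("gini of an empty node is undefined")
    p = counts / total
    return float(1.0 - (p * p).sum())


@dataclass
class TreeNode:
    """Binary CART node: internal (feature, threshold, children) or leaf
    (per-class sample counts in CLASS_ORDER)."""

    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    counts: tuple[int, int] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.counts is not None

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"counts": list(self.counts)}
        return {
            "feature": self.feature,
            "threshold": self.threshold,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        if "counts" in d:
            return cls(counts=tuple(d["counts"]))
        return cls(
            feature=d["feature"],
            threshold=d["threshold"],
            left=cls.from_dict(d["left"]),
            right=cls.from_dict(d["right"]),
        )


@dataclass(frozen=True)
class ForestParams:
    """Tunable hyperparameters.  m_try defaults to floor(sqrt(37)) = 6, the
    classical per-split feature-subset size; max_depth 0 means unlimited."""

    n_trees: int = 1000
    m_try: int = 6
    min_samples_split: int = 2
    max_depth: int = 0

    def __post_init__(self):
        if self.n_trees < 1 or self.m_try < 1 or self.min_samples_split < 2:
            raise ValueError(f"invalid forest parameters: {self}")
        if self.max_depth < 0:
            raise ValueError("max_depth must be >= 0 (0 = unlimited)")


@dataclass
class ForestModel:
    trees: list[TreeNode]
    params: ForestParams
    seed: int
    n_features: int
    class_order: tuple[str, str] = CLASS_ORDER

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def best_split(X: np.ndarray, y: np.ndarray,
               candidate_features: Sequence[int]) -> tuple[int, float, float] | None:
    """Best (feature, threshold, gain) over the candidate features.

    Thresholds are midpoints between consecutive distinct sorted values of a
    feature; gain is the weighted Gini decrease versus the parent.  Ties are
    broken toward the lowest feature index, then the lowest threshold.
    Returns None when no split achieves positive gain (pure node, or constant
    candidate features).
    """
    y = np.asarray(y)
    n = len(y)
    if n < 2:
        return None
    n1 = int(y.sum())  # class-1 count; y holds 0/1 class indices
    parent = gini((n - n1, n1))
    if parent == 0.0:
        return None

    best: tuple[int, float, float] | None = None
    for f in sorted(set(int(c) for c in candidate_features)):
        xs = X[:, f]
        order = np.argsort(xs, kind="stable")
        xs_s = xs[order]
        ys_s = y[order]
        # boundaries between distinct consecutive values
        diff = np.flatnonzero(xs_s[1:] > xs_s[:-1])
        if len(diff) == 0:
            continue
        left_n = diff + 1.0
        left_1 = np.cumsum(ys_s)[diff].astype(float)
        left_0 = left_n - left_1
        right_n = n - left_n
        right_1 = n1 - left_1
        right_0 = right_n - right_1
        g_left = 1.0 - ((left_0 / left_n) ** 2 + (left_1 / left_n) ** 2)
        g_right = 1.0 - ((right_0 / right_n) ** 2 + (right_1 / right_n) ** 2)
        gains = parent - (left_n * g_left + right_n * g_right) / n
        i = int(np.argmax(gains))  # first max -> lowest threshold on ties
        gain = float(gains[i])
        if gain <= _TIE_TOL:
            continue
        thr = float((xs_s[diff[i]] + xs_s[diff[i] + 1]) / 2.0)
        if best is None or gain > best[2] + _TIE_TOL:
            best = (f, thr, gain)
    return best


def _grow(X: np.ndarray, y: np.ndarray, params: ForestParams,
          rng: np.random.Generator, depth: int, n_features: int) -> TreeNode:
    n = len(y)
    n1 = int(y.sum())
    counts = (n - n1, n1)
    if (
        n < params.min_samples_split
        or n1 in (0, n)
        or (params.max_depth and depth >= params.max_depth)
    ):
        return TreeNode(counts=counts)
    m = min(params.m_try, n_features)
    candidates = rng.choice(n_features, size=m, replace=False)
    split = best_split(X, y, candidates)
    if split is None:
        return TreeNode(counts=counts)
    f, thr, _gain = split
    go_left = X[:, f] <= thr
    return TreeNode(
        feature=f,
        threshold=thr,
        left=_grow(X[go_left], y[go_left], params, rng, depth + 1, n_features),
        right=_grow(X[~go_left], y[~go_left], params, rng, depth + 1, n_features),
    )


def _encode_labels(y: Sequence[str]) -> np.ndarray:
    y = np.asarray(y, dtype=object)
    unknown = set(y) - set(CLASS_ORDER)
    if unknown:
        raise FitError(f"unknown class labels: {sorted(unknown)}")
    return (y == CLASS_ORDER[1]).astype(np.int64)


def fit_forest(X: np.ndarray, y: Sequence[str], params: ForestParams,
               seed: int, bootstrap: bool = True) -> ForestModel:
    """Fit the ensemble: each tree sees a with-replacement resample of size n
    and draws ``m_try`` features uniformly without replacement at every split.
    Deterministic under a fixed seed.  ``bootstrap=False`` trains every tree
    on the full sample (used for single-tree CART equivalence checks)."""
    X = np.asarray(X, dtype=float)
    yi = _encode_labels(y)
    if X.ndim != 2 or len(X) != len(yi):
        raise ShapeError(f"X must be 2-D matching y; got {X.shape} vs {len(yi)}")
    if len(yi) < 2:
        raise FitError("need at least 2 samples")
    if yi.min() == yi.max():
        raise FitError("training labels contain a single class")

    rng = np.random.default_rng(seed)
    n = len(yi)
    trees = []
    for _ in range(params.n_trees):
        idx = rng.integers(0, n, size=n) if bootstrap else np.arange(n)
        trees.append(_grow(X[idx], yi[idx], params, rng, 0, X.shape[1]))
    return ForestModel(trees, params, seed, X.shape[1])


def _tree_votes(node: TreeNode, X: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
    if node.is_leaf:
        # leaf vote: majority class, ties toward class 0 (odontogenic)
        out[idx] = 1 if node.counts[1] > node.counts[0] else 0
        return
    go_left = X[idx, node.feature] <= node.threshold
    _tree_votes(node.left, X, idx[go_left], out)
    _tree_votes(node.right, X, idx[~go_left], out)


def predict(model: ForestModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote across trees.

    Returns (labels, vote fractions) where the fraction is the share of trees
    voting odontogenic; exact 50/50 ties go to odontogenic, the majority
    class in the published case mix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.n_features:
        raise ShapeError(f"expected {model.n_features} features, got {X.shape[1]}")
    votes = np.zeros((len(model.trees), len(X)), dtype=np.int64)
    idx = np.arange(len(X))
    for t, root in enumerate(model.trees):
        _tree_votes(root, X, idx, votes[t])
    frac_odont = 1.0 - votes.mean(axis=0)
    labels = np.where(frac_odont >= 0.5, model.class_order[0], model.class_order[1])
    return labels.astype(object), frac_odont


# ---------------------------------------------------------------------------
# protocol: stratified split and grid search


def split_80_20(y: Sequence[str], seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified 80/20 index split; |train| = round(0.8 n), disjoint and
    exhaustive.  A class with fewer than 2 members triggers a warning and an
    unstratified fallback."""
    y = np.asarray(y, dtype=object)
    n = len(y)
    if n < 5:
        raise FitError("need at least 5 samples for an 80/20 split")
    n_train = int(round(0.8 * n))
    rng = np.random.default_rng(seed)

    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < 2:
        warnings.warn("a class has <2 members; falling back to an unstratified split")
        perm = rng.permutation(n)
        return np.sort(perm[:n_train]), np.sort(perm[n_train:])

    train_parts: list[np.ndarray] = []
    alloc: list[tuple[np.ndarray, int]] = []
    for cls, cnt in zip(classes, counts):
        idx = rng.permutation(np.flatnonzero(y == cls))
        alloc.append((idx, int(round(0.8 * cnt))))
    # adjust largest class so the overall train size is exactly round(0.8 n)
    drift = sum(k for _, k in alloc) - n_train
    if drift != 0:
        big = int(np.argmax(counts))
        alloc[big] = (alloc[big][0], alloc[big][1] - drift)
    for idx, k in alloc:
        train_parts.append(idx[:k])
    train = np.sort(np.concatenate(train_parts))
    test = np.sort(np.setdiff1d(np.arange(n), train))
    return train, test


def _f1(tp: int, fp: int, fn: int) -> float:
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def _macro_f1(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    scores = []
    for cls in CLASS_ORDER:
        tp = int(((y_true == cls) & (y_pred == cls)).sum())
        fp = int(((y_true != cls) & (y_pred == cls)).sum())
        fn = int(((y_true == cls) & (y_pred != cls)).sum())
        scores.append(_f1(tp, fp, fn))
    return float(np.mean(scores))


def grid_search(X: np.ndarray, y: Sequence[str], grid: Sequence[ForestParams],
                k: int = 5, seed: int = 0) -> tuple[ForestParams, list[dict]]:
    """Exhaustive grid search scored by k-fold cross-validated macro-F1.

    Fold assignment is a seeded permutation cut into k near-equal parts, fixed
    across cells.  A fold whose training part is single-class is skipped with
    a warning.  Ties go to the first cell in grid order.
    """
    if not grid:
        raise ValueError("grid must be non-empty")
    if k < 2:
        raise ValueError("need k >= 2 folds")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=object)
    n = len(y)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    folds = np.array_split(perm, k)
    fold_seeds = np.random.SeedSequence(seed).generate_state(len(grid) * k).reshape(len(grid), k)

    table: list[dict] = []
    best_i, best_score = 0, -np.inf
    for i, params in enumerate(grid):
        scores = []
        for j, val_idx in enumerate(folds):
            train_idx = np.setdiff1d(perm, val_idx)
            if len(np.unique(y[train_idx])) < 2 or len(val_idx) == 0:
                warnings.warn(f"fold {j} skipped: single-class training part")
                continue
            model = fit_forest(X[train_idx], y[train_idx], params, int(fold_seeds[i, j]))
            pred, _ = predict(model, X[val_idx])
            scores.append(_macro_f1(y[val_idx], pred))
        mean_score = float(np.mean(scores)) if scores else np.nan
        table.append({"params": params, "macro_f1": mean_score, "n_folds": len(scores)})
        if np.isfinite(mean_score) and mean_score > best_score + _TIE_TOL:
            best_i, best_score = i, mean_score
    return grid[best_i], table


def default_grid() -> list[ForestParams]:
    """The default search grid around the published winning setting
    (1000 trees, gini): n_trees x m_try x min_samples_split."""
    return [
        ForestParams(n_trees=nt, m_try=mt, min_samples_split=ms)
        for nt in (100, 500, 1000)
        for mt in (3, 6, 12)
        for ms in (2, 5)
    ]


# ---------------------------------------------------------------------------
# serialization

_FORMAT_VERSION = 1


def save_forest(model: ForestModel, path) -> None:
    payload = {
        "format_version": _FORMAT_VERSION,
        "params": asdict(model.params),
        "seed": model.seed,
        "n_features": model.n_features,
        "class_order": list(model.class_order),
        "trees": [t.to_dict() for t in model.trees],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_forest(path) -> ForestModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != _FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {payload.get('format_version')}")
    return ForestModel(
        trees=[TreeNode.from_dict(t) for t in payload["trees"]],
        params=ForestParams(**payload["params"]),
        seed=payload["seed"],
        n_features=payload["n_features"],
        class_order=tuple(payload["class_order"]),
    )
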