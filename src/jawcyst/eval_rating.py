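"""Diagnostic classification metrics and inter-rater agreement.

One-vs-rest confusion counts, the five standard diagnostic metrics
(sensitivity, specificity, PPV, NPV, F1) with undefined cells flagged as NaN
rather than zeroed, the two-class report whose exchange symmetry
(sens(A) = spec(B), ppv(A) = npv(B)) is an exact algebraic identity, Fleiss'
kappa with a percentile-bootstrap confidence interval over subjects, and
mean-Dice reporting for paired mask sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .overlap_features import dice
from .scene_sim import MaskSet, STRUCTURE_KEYS


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int
    target_class: str

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts must total > 0")


@dataclass(frozen=True)
class ClassMetrics:
    """The five diagnostic metrics; NaN marks an undefined cell (zero
    denominator), which is deliberately distinct from a true 0."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "f1": self.f1,
        }


def confusion_counts(truth, predicted, target_class: str) -> ConfusionCounts:
    """One-vs-rest counts for ``target_class``."""
    truth = np.asarray(truth, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if truth.shape != predicted.shape:
        raise ValueError(f"length mismatch: {truth.shape} vs {predicted.shape}")
    if truth.size == 0:
        raise ValueError("empty label vectors")
    t = truth == target_class
    p = predicted == target_class
    return ConfusionCounts(
        tp=int((t & p).sum()),
        fp=int((~t & p).sum()),
        tn=int((~t & ~p).sum()),
        fn=int((t & ~p).sum()),
        target_class=target_class,
    )


def _ratio(num: int, den: int) -> float:
    return num / den if den else np.nan


def f1_score(ppv: float, sensitivity: float) -> float:
    """Harmonic mean of precision and sensitivity (NaN propagates)."""
    if not (np.isfinite(ppv) and np.isfinite(sensitivity)):
        return np.nan
    if ppv + sensitivity == 0:
        return 0.0
    return 2.0 * ppv * sensitivity / (ppv + sensitivity)


def class_metrics(c: ConfusionCounts) -> ClassMetrics:
    sens = _ratio(c.tp, c.tp + c.fn)
    spec = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    npv = _ratio(c.tn, c.tn + c.fn)
    return ClassMetrics(sens, spec, ppv, npv, f1_score(ppv, sens))


def two_class_report(truth, predicted,
                     classes: tuple[str, str] | None = None) -> dict[str, ClassMetrics]:
    """Per-class one-vs-rest metrics for a two-class problem.

    With exactly two classes the confusion tables are transposes of each
    other, so sens(A) = spec(B) and ppv(A) = npv(B) hold exactly.
    """
    truth = np.asarray(truth, dtype=object)
    present = sorted(set(truth.tolist()))
    if classes is None:
        if len(present) != 2:
            raise ValueError(f"expected exactly two classes in truth, got {present}")
        classes = tuple(present)
    return {
        cls: class_metrics(confusion_counts(truth, predicted, cls)) for cls in classes
    }


def report_frame(report: dict[str, ClassMetrics]) -> pd.DataFrame:
    """Metrics-by-class table (metric rows, class columns)."""
    return pd.DataFrame({cls: m.as_dict() for cls, m in report.items()})


# ---------------------------------------------------------------------------
# inter-rater agreement


def fleiss_kappa(matrix) -> float:
    """Fleiss' kappa for a subjects x categories table of rater-vote counts.

    kappa = (P_bar - Pe_bar) / (1 - Pe_bar) with per-subject agreement
    P_i = (sum_j n_ij^2 - n) / (n (n - 1)) and chance agreement
    Pe_bar = sum_j p_j^2.  Every row must sum to the same rater count n >= 2.
    When every vote falls in one category Pe_bar = 1 and kappa is undefined
    (NaN, with a warning).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D table with >=2 subjects and >=2 categories")
    row_sums = m.sum(axis=1)
    n_raters = row_sums[0]
    if n_raters < 2 or not np.all(row_sums == n_raters):
        raise ValueError("every subject needs the same rater count >= 2")
    n_sub = m.shape[0]
    p_j = m.sum(axis=0) / (n_sub * n_raters)
    pe = float((p_j ** 2).sum())
    p_i = ((m ** 2).sum(axis=1) - n_raters) / (n_raters * (n_raters - 1))
    p_bar = float(p_i.mean())
    if pe >= 1.0:
        warnings.warn("all votes in a single category: kappa undefined")
        return np.nan
    return (p_bar - pe) / (1.0 - pe)


def kappa_bootstrap_ci(matrix, n_boot: int = 2000, level: float = 0.95,
                       seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for Fleiss' kappa, resampling subjects.

    Degenerate resamples (all votes in one category, kappa undefined) are
    dropped from the percentile computation.
    """
    if n_boot < 100:
        raise ValueError("need n_boot >= 100")
    m = np.asarray(matrix, dtype=float)
    rng = np.random.default_rng(seed)
    n_sub = m.shape[0]
    stats = np.empty(n_boot)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for b in range(n_boot):
            stats[b] = fleiss_kappa(m[rng.integers(0, n_sub, size=n_sub)])
    finite = stats[np.isfinite(stats)]
    if len(finite) == 0:
        return (np.nan, np.nan)
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(finite, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def ratings_to_matrix(ratings: pd.DataFrame,
                      categories: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Convert a subjects x raters label table into a vote-count matrix."""
    if categories is None:
        categories = sorted(set(ratings.to_numpy(dtype=object).ravel().tolist()))
    counts = np.zeros((len(ratings), len(categories)), dtype=int)
    for j, cat in enumerate(categories):
        counts[:, j] = (ratings == cat).sum(axis=1)
    return counts, categories


def rater_group_report(truth, ratings: pd.DataFrame,
                       categories: list[str]) -> pd.DataFrame:
    """Per-rater one-vs-rest metrics averaged across the rater panel.

    Metrics are computed per rater first and then summarized as mean and SD
    per category; averaging per-rater metrics (rather than pooling counts)
    is the reporting convention for heterogeneous human panels.
    """
    per_rater = []
    for col in ratings.columns:
        for cat in categories:
            m = class_metrics(confusion_counts(truth, ratings[col], cat))
            per_rater.append({"rater": col, "category": cat, **m.as_dict()})
    long = pd.DataFrame(per_rater)
    return long.groupby("category")[
        ["sensitivity", "specificity", "ppv", "npv", "f1"]
    ].agg(["mean", "std"])


# ---------------------------------------------------------------------------
# segmentation reporting


def dice_report(predicted: list[MaskSet], truth: list[MaskSet]) -> pd.Series:
    """Mean Dice per structure key across paired scenes.

    Structures absent in both prediction and truth score 1.0 by convention
    and are included in the mean.
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth mask-set lists differ in length")
    if not predicted:
        raise ValueError("empty mask-set lists")
    acc = {k: [] for k in STRUCTURE_KEYS}
    for pred, true in zip(predicted, truth):
        if pred.shape != true.shape:
            raise ValueError(f"mask shape mismatch: {pred.shape} vs {true.shape}")
        for k in STRUCTURE_KEYS:
            acc[k].append(dice(pred[k], true[k]))
    return pd.Series({k: float(np.mean(v)) for k, v in acc.items()}, name="mean_dice")
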