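"""Object-detection evaluation.

Greedy confidence-ordered matching of detections to ground-truth boxes at an
IoU threshold, 101-point interpolated average precision (COCO convention),
AP/AR averaged over IoU 0.50:0.05:0.95 with a per-image cap of 100
detections, and the translation of detections into image-level binary
classification across a confidence-threshold sweep.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .overlap_features import iou
from .scene_sim import BoundingBox, Detection

IOU_RANGE: tuple[float, ...] = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))
MAX_DETECTIONS_DEFAULT = 100


@dataclass
class MatchResult:
    """Outcome of matching one image's detections against its ground truth."""

    iou_threshold: float
    det_is_tp: list[bool]
    det_matched_gt: list[int | None]  # index into the ground-truth list
    det_confidence: list[float]
    gt_matched: list[bool]

    @property
    def n_tp(self) -> int:
        return sum(self.det_is_tp)


@dataclass
class DetectionMetrics:
    """Headline detection numbers at a range of IoU thresholds."""

    ap_at_iou: dict[float, float]
    ar_at_iou: dict[float, float]
    mean_ap_range: float
    ar_range: float
    max_detections: int = MAX_DETECTIONS_DEFAULT


def _sorted_capped(detections: list[Detection], max_detections: int) -> list[Detection]:
    ordered = sorted(
        detections, key=lambda d: (-d.confidence, -d.box.area, d.box.x, d.box.y)
    )
    return ordered[:max_detections]


def match_detections(detections: list[Detection], ground_truths: list[BoundingBox],
                     iou_threshold: float,
                     max_detections: int = MAX_DETECTIONS_DEFAULT) -> MatchResult:
    """Greedy one-to-one matching in descending confidence order.

    Each detection claims the unmatched ground truth with the highest IoU,
    provided that IoU reaches the threshold; otherwise it is a false
    positive.  Each ground truth can be claimed at most once, so a duplicate
    detection of an already-matched lesion counts against precision.
    """
    dets = _sorted_capped(detections, max_detections)
    taken = [False] * len(ground_truths)
    is_tp: list[bool] = []
    matched: list[int | None] = []
    for det in dets:
        best_j, best_iou = None, 0.0
        for j, gt in enumerate(ground_truths):
            if taken[j]:
                continue
            v = iou(det.box, gt)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j is not None and best_iou >= iou_threshold:
            taken[best_j] = True
            is_tp.append(True)
            matched.append(best_j)
        else:
            is_tp.append(False)
            matched.append(None)
    return MatchResult(
        iou_threshold=iou_threshold,
        det_is_tp=is_tp,
        det_matched_gt=matched,
        det_confidence=[d.confidence for d in dets],
        gt_matched=taken,
    )


def average_precision(matches: list[MatchResult]) -> float:
    """101-point interpolated AP pooled over images.

    Detections from all images are ranked by descending confidence; precision
    is interpolated to its running maximum from the right and sampled at the
    101 recall points 0.00, 0.01, ..., 1.00.
    """
    n_gt = sum(len(m.gt_matched) for m in matches)
    if n_gt == 0:
        raise DegenerateInputError("AP is undefined without ground-truth objects")
    confs = np.array([c for m in matches for c in m.det_confidence])
    flags = np.array([f for m in matches for f in m.det_is_tp], dtype=bool)
    if len(confs) == 0:
        return 0.0
    order = np.argsort(-confs, kind="stable")
    tp = np.cumsum(flags[order])
    fp = np.cumsum(~flags[order])
    recall = tp / n_gt
    precision = tp / (tp + fp)
    # monotone envelope from the right, then sample the 101 recall points
    envelope = np.maximum.accumulate(precision[::-1])[::-1]
    points = np.linspace(0.0, 1.0, 101)
    idx = np.searchsorted(recall, points, side="left")
    sampled = np.where(idx < len(envelope), envelope[np.minimum(idx, len(envelope) - 1)], 0.0)
    return float(sampled.mean())


def ap_ar_over_range(dataset: list[tuple[list[Detection], list[BoundingBox]]],
                     iou_range: tuple[float, ...] = IOU_RANGE,
                     max_detections: int = MAX_DETECTIONS_DEFAULT) -> DetectionMetrics:
    """AP and AR at each IoU threshold in the range, plus their means.

    AR at a threshold is matched ground truths over total ground truths with
    the per-image detections cap applied (the usual "AR@100" with one box
    class).  ``dataset`` is a list of (detections, ground-truth boxes) pairs,
    one per image; lesion-free images contribute only false positives.
    """
    ap_at: dict[float, float] = {}
    ar_at: dict[float, float] = {}
    for thr in iou_range:
        matches = [
            match_detections(dets, gts, thr, max_detections) for dets, gts in dataset
        ]
        ap_at[thr] = average_precision(matches)
        n_gt = sum(len(m.gt_matched) for m in matches)
        n_matched = sum(sum(m.gt_matched) for m in matches)
        ar_at[thr] = n_matched / n_gt if n_gt else np.nan
    return DetectionMetrics(
        ap_at_iou=ap_at,
        ar_at_iou=ar_at,
        mean_ap_range=float(np.mean(list(ap_at.values()))),
        ar_range=float(np.mean(list(ar_at.values()))),
        max_detections=max_detections,
    )


def image_level_sweep(dataset: list[tuple[list[Detection], bool]],
                      thresholds: list[float]) -> pd.DataFrame:
    """Translate detections into image-level binary calls per threshold.

    An image is called positive iff it has at least one detection with
    confidence >= t.  Emits accuracy, precision, sensitivity, specificity and
    F1 per threshold; without negative images specificity (and accuracy's
    denominator still works) is undefined and reported as NaN with a warning.
    The positive-call count is non-increasing in t by construction.
    """
    has_neg = any(not pos for _, pos in dataset)
    if not has_neg:
        warnings.warn("no lesion-free images: specificity is undefined")
    rows = []
    for t in thresholds:
        tp = fp = tn = fn = 0
        for detections, is_positive in dataset:
            called = any(d.confidence >= t for d in detections)
            if is_positive and called:
                tp += 1
            elif is_positive:
                fn += 1
            elif called:
                fp += 1
            else:
                tn += 1
        n = tp + fp + tn + fn
        precision = tp / (tp + fp) if tp + fp else np.nan
        sensitivity = tp / (tp + fn) if tp + fn else np.nan
        specificity = tn / (tn + fp) if tn + fp else np.nan
        f1 = (
            2 * precision * sensitivity / (precision + sensitivity)
            if np.isfinite(precision) and np.isfinite(sensitivity) and precision + sensitivity > 0
            else np.nan
        )
        rows.append({
            "threshold": t, "n_positive_calls": tp + fp,
            "tp": tp, "fp": fp, "tn": tn, "fn": fn,
            "accuracy": (tp + tn) / n if n else np.nan,
            "precision": precision, "sensitivity": sensitivity,
            "specificity": specificity, "f1": f1,
        })
    return pd.DataFrame(rows)
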