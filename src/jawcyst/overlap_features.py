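"""Geometric overlap quantities and the per-sample feature vector.

The classifier's input is purely spatial context: for the single
highest-confidence lesion box, the share of its area covered by each
anatomical segmentation mask — five region features (maxilla, mandible,
merged mandibular canals, merged maxillary sinuses, dentition) followed by
one feature per FDI tooth position, 37 ratios in [0, 1] in a fixed order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .scene_sim import (
    REGION_KEYS,
    STRUCTURE_KEYS,
    TOOTH_KEYS,
    BoundingBox,
    Detection,
    MaskSet,
)

#: Canonical feature order: 5 region features then the 32 FDI tooth slots.
FEATURE_NAMES: tuple[str, ...] = STRUCTURE_KEYS

N_FEATURES = len(FEATURE_NAMES)  # 37

_DENTITION_TOL = 1e-9


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes, counted in whole pixels."""
    ix = max(0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def overlap_share(box: BoundingBox, mask: np.ndarray) -> float:
    """Share of the box's area covered by set mask pixels.

    The box is clipped to the grid first and the clipped area is the
    denominator; a box entirely outside the grid is degenerate.
    """
    mask = np.asarray(mask)
    clipped = box.clip(mask.shape[1], mask.shape[0])
    if clipped is None:
        raise DegenerateInputError(
            f"box {box} clips to zero area on a {mask.shape} grid"
        )
    sub = mask[clipped.y:clipped.y2, clipped.x:clipped.x2]
    return float(np.count_nonzero(sub)) / clipped.area


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice coefficient 2|a∩b| / (|a|+|b|); two empty masks score 1.0
    (perfect agreement that the structure is absent)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    total = int(a.sum()) + int(b.sum())
    if total == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / total


def select_top_detection(detections: list[Detection], threshold: float) -> Detection | None:
    """Highest-confidence detection at or above the confidence threshold.

    Ties are broken by larger box area, then by lowest (x, y). None means the
    sample is dropped downstream (detector reported nothing usable at this
    threshold — the source of sample attrition in the threshold sweep).
    """
    eligible = [d for d in detections if d.confidence >= threshold]
    if not eligible:
        return None
    return max(eligible, key=lambda d: (d.confidence, d.box.area, -d.box.x, -d.box.y))


def select_top_box(detections: list[Detection], threshold: float) -> BoundingBox | None:
    det = select_top_detection(detections, threshold)
    return det.box if det is not None else None


@dataclass(frozen=True)
class OverlapFeatureVector:
    """The 37 box/mask overlap shares for one sample, in canonical order."""

    sample_id: str
    source: str  # "predicted_box" | "annotated_box"
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got shape {v.shape}")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("overlap features must lie in [0, 1]")
        dent = v[FEATURE_NAMES.index("dentition")]
        tooth_max = v[len(REGION_KEYS):].max(initial=0.0)
        if dent < tooth_max - _DENTITION_TOL:
            raise ValueError(
                f"dentition share {dent} below max tooth share {tooth_max}: "
                "dentition must be the union of the teeth"
            )

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])


def feature_vector(box: BoundingBox, masks: MaskSet, sample_id: str,
                   source: str = "annotated_box") -> OverlapFeatureVector:
    """Overlap share of the box with every structure mask, canonical order.

    The canal and sinus grids already hold the left/right union, so each
    yields the single merged feature.
    """
    values = np.array([overlap_share(box, masks[k]) for k in FEATURE_NAMES])
    return OverlapFeatureVector(sample_id, source, values)


# ---------------------------------------------------------------------------
# feature tables


def feature_table(vectors: list[OverlapFeatureVector],
                  labels: list[str] | None = None,
                  confidences: list[float] | None = None) -> pd.DataFrame:
    """Assemble feature vectors into the CSV-ready table layout:
    sample_id, source, 37 feature columns, label, confidence."""
    rows = {
        "sample_id": [v.sample_id for v in vectors],
        "source": [v.source for v in vectors],
    }
    stacked = (
        np.stack([v.values for v in vectors])
        if vectors else np.empty((0, N_FEATURES))
    )
    for j, name in enumerate(FEATURE_NAMES):
        rows[name] = stacked[:, j]
    rows["label"] = labels if labels is not None else [""] * len(vectors)
    rows["confidence"] = confidences if confidences is not None else [np.nan] * len(vectors)
    return pd.DataFrame(rows)


def write_feature_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def read_feature_table(path) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Load a feature CSV; returns (X, labels, full table)."""
    df = pd.read_csv(path)
    X = df[list(FEATURE_NAMES)].to_numpy(dtype=float)
    y = df["label"].to_numpy(dtype=object)
    return X, y, df
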