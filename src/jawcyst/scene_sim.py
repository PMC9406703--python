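"""Synthetic jaw-scene simulator.

Generates seeded 2-D "cartoon" panoramic-radiograph scenes: binary anatomy
masks (maxilla, mandible, mandibular canals, maxillary sinuses, dentition and
32 individual teeth in FDI numbering), cystic lesions as bounding boxes with a
planted class rule, plus simulated imperfect detector and segmenter outputs.

The planted structure mirrors how the two diagnostic classes are defined
radiologically: an odontogenic lesion is placed over a tooth apex so its box
overlaps that tooth's mask, while a non-odontogenic lesion is placed in jaw
bone or sinus with zero overlap with every individual tooth.  On noise-free
scenes the rule "odontogenic iff any tooth-overlap feature > 0" is therefore
exact, which makes every downstream stage testable without real radiographs.

Only the spatial-overlap topology matters downstream, so anatomy is drawn as
filled parametric shapes (bands, trapezoids, ellipses, slanted canal strips),
not as photorealistic structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .errors import (
    AnnotationParseError,
    DegenerateInputError,
    PlacementError,
)

# ---------------------------------------------------------------------------
# canonical structure keys

#: FDI two-digit tooth codes in canonical feature order:
#: upper right (11-18), upper left (21-28), lower left (31-38), lower right (41-48).
FDI_TEETH: tuple[int, ...] = tuple(
    10 * q + i for q in (1, 2, 3, 4) for i in range(1, 9)
)

TOOTH_KEYS: tuple[str, ...] = tuple(f"tooth_{t}" for t in FDI_TEETH)

#: Region keys preceding the tooth block in the canonical feature order.
REGION_KEYS: tuple[str, ...] = (
    "maxilla",
    "mandible",
    "mandibular_canal",
    "maxillary_sinus",
    "dentition",
)

STRUCTURE_KEYS: tuple[str, ...] = REGION_KEYS + TOOTH_KEYS

ODONTOGENIC = "odontogenic"
NON_ODONTOGENIC = "non_odontogenic"
CYST_CLASSES: tuple[str, str] = (ODONTOGENIC, NON_ODONTOGENIC)

#: Published mean Dice of the anatomy segmentation models, used as the default
#: degradation targets for the simulated segmenter.  Dentition is not listed:
#: it is rebuilt as the union of the degraded individual teeth so that the
#: MaskSet invariant (dentition == union of teeth) survives degradation.
DEFAULT_DICE_TARGETS: dict[str, float] = {
    "maxilla": 0.465,
    "mandible": 0.978,
    "mandibular_canal": 0.794,
    "maxillary_sinus": 0.644,
    "tooth": 0.870,
}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open: columns [x, x+w), rows [y, y+h)."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box must have positive extent, got w={self.w} h={self.h}")

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    @property
    def area(self) -> int:
        return self.w * self.h

    def clip(self, width: int, height: int) -> "BoundingBox | None":
        """Clip to an image frame; None if nothing remains."""
        x1, y1 = max(self.x, 0), max(self.y, 0)
        x2, y2 = min(self.x2, width), min(self.y2, height)
        if x2 <= x1 or y2 <= y1:
            return None
        return BoundingBox(x1, y1, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class Detection:
    """A candidate lesion box with a confidence score."""

    box: BoundingBox
    confidence: float
    label: str = "cyst"

    def __post_init__(self):
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


class MaskSet:
    """One binary pixel grid per anatomical structure, all sharing one shape.

    Keys are :data:`STRUCTURE_KEYS`; the left/right mandibular canals and
    maxillary sinuses are stored merged under their singular key, matching the
    single per-structure overlap feature computed downstream.  Absent teeth
    keep an all-zero grid so the 32-slot feature layout is fixed.
    """

    def __init__(self, grids: dict[str, np.ndarray]):
        shapes = {g.shape for g in grids.values()}
        if len(shapes) > 1:
            raise ValueError(f"mask grids disagree on shape: {shapes}")
        missing = set(STRUCTURE_KEYS) - set(grids)
        if missing:
            raise ValueError(f"missing structure grids: {sorted(missing)}")
        self._grids = {k: grids[k].astype(bool) for k in STRUCTURE_KEYS}

    def __getitem__(self, key: str) -> np.ndarray:
        return self._grids[key]

    def __contains__(self, key: str) -> bool:
        return key in self._grids

    def keys(self) -> tuple[str, ...]:
        return STRUCTURE_KEYS

    def items(self):
        return self._grids.items()

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self._grids.values())).shape

    def present_teeth(self) -> list[str]:
        return [k for k in TOOTH_KEYS if self._grids[k].any()]

    def validate(self) -> None:
        union = np.zeros(self.shape, dtype=bool)
        for k in TOOTH_KEYS:
            union |= self._grids[k]
        if not np.array_equal(union, self._grids["dentition"]):
            raise ValueError("dentition grid is not the union of tooth grids")


@dataclass(frozen=True)
class SceneConfig:
    """Layout and sampling parameters for one synthetic scene.

    Lesion class mix defaults to the published case mix (~72% of classifiable
    cysts odontogenic); demographics default to the published cohort (median
    age ~53.5 y, 41% female) and are carried only for annotation-file
    round-trips.
    """

    width: int = 512
    height: int = 256
    n_lesions: int = 1
    p_odontogenic: float = 0.72
    present_teeth: tuple[int, ...] | None = None  # None = all 32 FDI positions
    n_missing_teeth: int = 0  # random removals when present_teeth is None
    lesion_size_range: tuple[int, int] = (28, 56)
    max_attempts: int = 200

    def __post_init__(self):
        if not 0.0 <= self.p_odontogenic <= 1.0:
            raise ValueError("p_odontogenic must be in [0,1]")
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        if self.present_teeth is not None:
            bad = set(self.present_teeth) - set(FDI_TEETH)
            if bad:
                raise ValueError(f"unknown FDI tooth codes: {sorted(bad)}")


@dataclass(frozen=True)
class NoiseConfig:
    """Imperfection model for the simulated detector and segmenter.

    ``jitter_sd`` perturbs both box corners with i.i.d. Gaussian noise;
    ``fn_rate``/``fp_rate`` are per-lesion / per-scene Bernoulli probabilities;
    confidences follow Beta laws with true positives stochastically larger;
    ``dice_targets`` set the per-structure Dice the degraded masks should hit
    (key ``"tooth"`` applies to every individual tooth).
    """

    jitter_sd: float = 3.0
    fn_rate: float = 0.1
    fp_rate: float = 0.1
    tp_confidence: tuple[float, float] = (8.0, 2.0)
    fp_confidence: tuple[float, float] = (2.0, 5.0)
    dice_targets: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DICE_TARGETS)
    )

    def __post_init__(self):
        object.__setattr__(self, "tp_confidence", tuple(self.tp_confidence))
        object.__setattr__(self, "fp_confidence", tuple(self.fp_confidence))
        for name, rate in (("fn_rate", self.fn_rate), ("fp_rate", self.fp_rate)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {rate}")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be >= 0")
        for key, d in self.dice_targets.items():
            if not 0.2 < d <= 1.0:
                raise ValueError(f"dice target for {key!r} must be in (0.2, 1.0], got {d}")

    def dice_target_for(self, key: str) -> float | None:
        if key in self.dice_targets:
            return self.dice_targets[key]
        if key.startswith("tooth_"):
            return self.dice_targets.get("tooth")
        return None

    @classmethod
    def noise_free(cls) -> "NoiseConfig":
        return cls(jitter_sd=0.0, fn_rate=0.0, fp_rate=0.0, dice_targets={})


@dataclass(frozen=True)
class Scene:
    """Ground truth for one synthetic jaw image."""

    scene_id: str
    width: int
    height: int
    masks: MaskSet | None  # None on "light" copies that dropped pixel data
    lesions: tuple[tuple[BoundingBox, str], ...]  # (box, cyst class)
    age: int
    sex: str  # "F" | "M"

    def has_lesion(self) -> bool:
        return len(self.lesions) > 0


# ---------------------------------------------------------------------------
# anatomy drawing


def _tooth_polygon(grid: np.ndarray, cx: int, jaw: str, crown_y: int,
                   tooth_h: int, crown_w: int, root_w: int) -> None:
    """Fill a rounded-trapezoid tooth: wide at the crown, narrow at the apex.

    Upper teeth point their apex up (roots in the maxilla); lower teeth point
    down (roots in the mandible).
    """
    for i in range(tooth_h):
        frac = i / max(tooth_h - 1, 1)  # 0 at crown, 1 at apex
        half = max(int(round((crown_w * (1 - frac) + root_w * frac) / 2)), 1)
        y = crown_y - i if jaw == "upper" else crown_y + i
        if 0 <= y < grid.shape[0]:
            grid[y, max(cx - half, 0):min(cx + half + 1, grid.shape[1])] = True


def _ellipse(shape: tuple[int, int], cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def _canal_strip(shape: tuple[int, int], x_from: int, x_to: int,
                 y_from: float, y_to: float, thickness: int) -> np.ndarray:
    """Slanted strip of given vertical thickness between two endpoints."""
    grid = np.zeros(shape, dtype=bool)
    xs = np.arange(min(x_from, x_to), max(x_from, x_to))
    if x_to == x_from:
        return grid
    centers = y_from + (xs - x_from) * (y_to - y_from) / (x_to - x_from)
    half = thickness / 2
    for x, c in zip(xs, centers):
        lo = max(int(round(c - half)), 0)
        hi = min(int(round(c + half)) + 1, shape[0])
        grid[lo:hi, x] = True
    return grid


def _layout_anatomy(config: SceneConfig, present: Sequence[int]) -> MaskSet:
    """Draw all anatomy grids for one scene (deterministic given config)."""
    W, H = config.width, config.height
    shape = (H, W)
    sx, sy = W / 512.0, H / 256.0  # reference layout is 512x256

    def X(v: float) -> int:
        return int(round(v * sx))

    def Y(v: float) -> int:
        return int(round(v * sy))

    grids: dict[str, np.ndarray] = {k: np.zeros(shape, dtype=bool) for k in STRUCTURE_KEYS}

    # jaws: maxilla is a central upper band; the mandible is a lower band plus
    # two rami rising at the image edges (large tooth-free bone areas).
    grids["maxilla"][Y(34):Y(112), X(88):X(424)] = True
    mandible = np.zeros(shape, dtype=bool)
    mandible[Y(140):Y(228), X(34):X(478)] = True
    mandible[Y(64):Y(228), X(34):X(74)] = True
    mandible[Y(64):Y(228), X(438):X(478)] = True
    grids["mandible"] = mandible

    # paired structures stored merged (left/right union)
    sinus = _ellipse(shape, Y(62), X(150), Y(22), X(42)) | _ellipse(
        shape, Y(62), X(362), Y(22), X(42)
    )
    grids["maxillary_sinus"] = sinus & grids["maxilla"]
    canal = _canal_strip(shape, X(54), X(250), Y(190), Y(210), max(Y(7), 3)) | _canal_strip(
        shape, X(262), X(458), Y(210), Y(190), max(Y(7), 3)
    )
    grids["mandibular_canal"] = canal & grids["mandible"]

    # dentition: 16 teeth per arch along the occlusal plane.  Image left is the
    # patient's right, so the upper row runs 18..11 then 21..28 and the lower
    # row 48..41 then 31..38.
    occlusal = Y(128)
    tooth_h, crown_w, root_w = Y(44), X(13), X(7)
    pitch = X(22)
    row_start = X(80) + pitch // 2
    upper_row = [10 + i for i in range(8, 0, -1)] + [20 + i for i in range(1, 9)]
    lower_row = [40 + i for i in range(8, 0, -1)] + [30 + i for i in range(1, 9)]
    present_set = set(present)
    for idx, fdi in enumerate(upper_row):
        if fdi in present_set:
            _tooth_polygon(grids[f"tooth_{fdi}"], row_start + idx * pitch,
                           "upper", occlusal - 1, tooth_h, crown_w, root_w)
    for idx, fdi in enumerate(lower_row):
        if fdi in present_set:
            _tooth_polygon(grids[f"tooth_{fdi}"], row_start + idx * pitch,
                           "lower", occlusal + Y(4), tooth_h, crown_w, root_w)

    dentition = np.zeros(shape, dtype=bool)
    for k in TOOTH_KEYS:
        dentition |= grids[k]
    grids["dentition"] = dentition
    return MaskSet(grids)


def _tooth_apex(mask: np.ndarray, fdi: int) -> tuple[int, int]:
    """(x, y) of the root tip: topmost row for upper teeth, bottom for lower."""
    rows = np.flatnonzero(mask.any(axis=1))
    row = rows[0] if fdi < 30 else rows[-1]  # quadrants 1/2 point up
    cols = np.flatnonzero(mask[row])
    return int(cols.mean().round()), int(row)


# ---------------------------------------------------------------------------
# lesion placement


def _overlap_share_raw(box: BoundingBox, mask: np.ndarray) -> float:
    clipped = box.clip(mask.shape[1], mask.shape[0])
    if clipped is None:
        return 0.0
    sub = mask[clipped.y:clipped.y2, clipped.x:clipped.x2]
    return float(sub.sum()) / clipped.area


def _place_odontogenic(masks: MaskSet, config: SceneConfig,
                       rng: np.random.Generator, scene_id: str) -> BoundingBox:
    present = masks.present_teeth()
    if not present:
        raise PlacementError(scene_id, ODONTOGENIC, 0)
    lo, hi = config.lesion_size_range
    for _ in range(config.max_attempts):
        key = present[rng.integers(len(present))]
        fdi = int(key.split("_")[1])
        ax, ay = _tooth_apex(masks[key], fdi)
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        # center near the apex, nudged toward the root so the box reliably
        # covers >= 10% tooth area (the class's planted signature)
        shift = h // 4 if fdi < 30 else -h // 4
        cx = ax + int(rng.integers(-6, 7))
        cy = ay + shift + int(rng.integers(-4, 5))
        x = min(max(cx - w // 2, 0), config.width - w)
        y = min(max(cy - h // 2, 0), config.height - h)
        box = BoundingBox(x, y, w, h)
        if _overlap_share_raw(box, masks[key]) >= 0.10:
            return box
    raise PlacementError(scene_id, ODONTOGENIC, config.max_attempts)


def _place_non_odontogenic(masks: MaskSet, config: SceneConfig,
                           rng: np.random.Generator, scene_id: str) -> BoundingBox:
    allowed = (masks["maxilla"] | masks["mandible"] | masks["maxillary_sinus"]) & ~masks["dentition"]
    ys, xs = np.nonzero(allowed)
    if len(ys) == 0:
        raise PlacementError(scene_id, NON_ODONTOGENIC, 0)
    lo, hi = config.lesion_size_range
    for _ in range(config.max_attempts):
        i = rng.integers(len(ys))
        cx, cy = int(xs[i]), int(ys[i])
        w = int(rng.integers(lo, hi + 1))
        h = int(rng.integers(lo, hi + 1))
        x = min(max(cx - w // 2, 0), config.width - w)
        y = min(max(cy - h // 2, 0), config.height - h)
        box = BoundingBox(x, y, w, h)
        if _overlap_share_raw(box, masks["dentition"]) == 0.0:
            return box
    raise PlacementError(scene_id, NON_ODONTOGENIC, config.max_attempts)


def generate_scene(config: SceneConfig, seed: int, scene_id: str | None = None) -> Scene:
    """Generate one scene; bit-identical for identical ``(config, seed)``.

    Raises :class:`PlacementError` if a lesion cannot satisfy its class's
    overlap rule within ``config.max_attempts`` rejection samples.
    """
    rng = np.random.default_rng(seed)
    sid = scene_id if scene_id is not None else f"scene_{seed:08d}"

    if config.present_teeth is not None:
        present: list[int] = list(config.present_teeth)
    else:
        present = list(FDI_TEETH)
        if config.n_missing_teeth > 0:
            drop = rng.choice(len(present), size=config.n_missing_teeth, replace=False)
            present = [t for i, t in enumerate(present) if i not in set(drop.tolist())]

    masks = _layout_anatomy(config, present)

    lesions: list[tuple[BoundingBox, str]] = []
    for _ in range(config.n_lesions):
        cls = ODONTOGENIC if rng.random() < config.p_odontogenic else NON_ODONTOGENIC
        if cls == ODONTOGENIC:
            box = _place_odontogenic(masks, config, rng, sid)
        else:
            box = _place_non_odontogenic(masks, config, rng, sid)
        lesions.append((box, cls))

    age = int(np.clip(round(rng.normal(53.5, 16.0)), 18, 90))
    sex = "F" if rng.random() < 0.41 else "M"
    return Scene(sid, config.width, config.height, masks, tuple(lesions), age, sex)


# ---------------------------------------------------------------------------
# simulated detector


def _jitter_box(box: BoundingBox, sd: float, rng: np.random.Generator,
                width: int, height: int) -> BoundingBox:
    if sd == 0:
        return box
    dx1, dy1, dx2, dy2 = rng.normal(0.0, sd, size=4)
    x1 = int(np.clip(round(box.x + dx1), 0, width - 1))
    y1 = int(np.clip(round(box.y + dy1), 0, height - 1))
    x2 = int(np.clip(round(box.x2 + dx2), x1 + 1, width))
    y2 = int(np.clip(round(box.y2 + dy2), y1 + 1, height))
    return BoundingBox(x1, y1, x2 - x1, y2 - y1)


def simulate_detections(scene: Scene, noise: NoiseConfig, seed: int) -> list[Detection]:
    """Emit imperfect detections for a scene's ground-truth lesions.

    Each lesion is dropped with probability ``fn_rate``, otherwise emitted
    with Gaussian-jittered corners (clipped to the frame) and a confidence
    from the true-positive Beta law.  With probability ``fp_rate`` one
    additional spurious box is emitted with the (lower) false-positive
    confidence law.  The result is sorted by descending confidence.
    """
    rng = np.random.default_rng(seed)
    out: list[Detection] = []
    for box, _cls in scene.lesions:
        if rng.random() < noise.fn_rate:
            continue
        jittered = _jitter_box(box, noise.jitter_sd, rng, scene.width, scene.height)
        conf = float(rng.beta(*noise.tp_confidence))
        out.append(Detection(jittered, conf))
    if rng.random() < noise.fp_rate:
        w = int(rng.integers(20, 61))
        h = int(rng.integers(20, 61))
        x = int(rng.integers(0, scene.width - w))
        y = int(rng.integers(0, scene.height - h))
        conf = float(rng.beta(*noise.fp_confidence))
        out.append(Detection(BoundingBox(x, y, w, h), conf))
    out.sort(key=lambda d: (-d.confidence, -d.box.area, d.box.x, d.box.y))
    return out


# ---------------------------------------------------------------------------
# simulated segmenter


def degrade_mask(mask: np.ndarray, target_dice: float, seed: int) -> np.ndarray:
    """Degrade a binary mask so dice(original, degraded) ~= ``target_dice``.

    Exchanges k = round(n * (1 - d)) pixels: the k foreground pixels shallowest
    from the boundary are removed (distance-transform order, seeded tie-break)
    and the k background pixels nearest the mask are added, so the degraded
    mask keeps size n and the achieved Dice is (n - k)/n — within rounding of
    the target, and an erosion-plus-outward-smear pattern that resembles how a
    segmentation network misses boundaries.
    """
    if not 0.2 < target_dice <= 1.0:
        raise ValueError(f"target_dice must be in (0.2, 1.0], got {target_dice}")
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise DegenerateInputError("cannot degrade an empty mask")
    if target_dice == 1.0:
        return mask.copy()

    rng = np.random.default_rng(seed)
    k = int(round(n * (1.0 - target_dice)))
    if k == 0:
        return mask.copy()

    # work on the mask's bounding box (plus a margin wide enough to hold the
    # k added pixels) so distance transforms stay cheap on sparse structures
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    margin = int(math.ceil(math.sqrt(k))) + 8
    r0, r1 = max(rows[0] - margin, 0), min(rows[-1] + margin + 1, mask.shape[0])
    c0, c1 = max(cols[0] - margin, 0), min(cols[-1] + margin + 1, mask.shape[1])
    crop = mask[r0:r1, c0:c1]

    out_crop = crop.copy()
    # remove: order foreground by depth from boundary, shallowest first
    depth = ndimage.distance_transform_edt(crop)
    fg = np.flatnonzero(crop.ravel())
    order = np.lexsort((rng.random(len(fg)), depth.ravel()[fg]))
    out_crop.ravel()[fg[order[:k]]] = False
    # add: order background by distance to the original mask, nearest first
    dist = ndimage.distance_transform_edt(~crop)
    bg = np.flatnonzero(~crop.ravel())
    order = np.lexsort((rng.random(len(bg)), dist.ravel()[bg]))
    out_crop.ravel()[bg[order[: min(k, len(bg))]]] = True

    out = mask.copy()
    out[r0:r1, c0:c1] = out_crop
    return out


def degrade_maskset(masks: MaskSet, noise: NoiseConfig, seed: int) -> MaskSet:
    """Degrade every structure grid to its configured Dice target.

    Teeth are degraded individually (target ``"tooth"``); the dentition grid is
    then rebuilt as the union of the degraded teeth so the MaskSet invariant is
    preserved — its Dice is emergent, not separately targeted.  Structures
    without a target (or empty grids, e.g. absent teeth) pass through.
    """
    seeds = np.random.SeedSequence(seed).generate_state(len(STRUCTURE_KEYS))
    grids: dict[str, np.ndarray] = {}
    for key, sub_seed in zip(STRUCTURE_KEYS, seeds):
        grid = masks[key]
        target = noise.dice_target_for(key)
        if key == "dentition" or target is None or not grid.any():
            grids[key] = grid.copy()
        else:
            grids[key] = degrade_mask(grid, target, int(sub_seed))
    dentition = np.zeros(masks.shape, dtype=bool)
    for k in TOOTH_KEYS:
        dentition |= grids[k]
    grids["dentition"] = dentition
    return MaskSet(grids)


# ---------------------------------------------------------------------------
# plain-text annotation dialect

_ANNOTATION_HEADER = "scene_id\tx\ty\tw\th\tage\tsex\tdiagnosis"


@dataclass(frozen=True)
class LesionRecord:
    """One line of the plain-text annotation file."""

    scene_id: str
    box: BoundingBox
    age: int
    sex: str
    diagnosis: str


def write_annotation_file(scenes: Scene | Iterable[Scene], path) -> None:
    """Write the tab-separated annotation dialect: one line per lesion with
    the box's upper-left corner, width and height, plus age/sex/diagnosis.
    A lesion-free scene contributes no lines (header only if alone)."""
    if isinstance(scenes, Scene):
        scenes = [scenes]
    lines = [_ANNOTATION_HEADER]
    for scene in scenes:
        for box, cls in scene.lesions:
            lines.append(
                f"{scene.scene_id}\t{box.x}\t{box.y}\t{box.w}\t{box.h}"
                f"\t{scene.age}\t{scene.sex}\t{cls}"
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_annotation_file(path) -> list[LesionRecord]:
    """Parse the annotation dialect back into records.

    Raises :class:`AnnotationParseError` (with the line number) on malformed
    lines, including boxes violating the positive-extent invariant.
    """
    records: list[LesionRecord] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0] != _ANNOTATION_HEADER:
        raise AnnotationParseError(path, 1, "missing or malformed header")
    for line_no, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 8:
            raise AnnotationParseError(path, line_no, f"expected 8 fields, got {len(parts)}")
        sid, xs, ys, ws, hs, ages, sex, diagnosis = parts
        try:
            x, y, w, h, age = int(xs), int(ys), int(ws), int(hs), int(ages)
        except ValueError as exc:
            raise AnnotationParseError(path, line_no, f"non-integer field: {exc}") from exc
        if w <= 0 or h <= 0:
            raise AnnotationParseError(path, line_no, f"non-positive box extent w={w} h={h}")
        if diagnosis not in CYST_CLASSES:
            raise AnnotationParseError(path, line_no, f"unknown diagnosis {diagnosis!r}")
        records.append(LesionRecord(sid, BoundingBox(x, y, w, h), age, sex, diagnosis))
    return records
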