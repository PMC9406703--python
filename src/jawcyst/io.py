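"""File interchange: PNG mask sets and COCO-style detection JSON."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .scene_sim import (
    STRUCTURE_KEYS,
    BoundingBox,
    Detection,
    MaskSet,
    Scene,
)

CATEGORY_ID_CYST = 1


def save_masks(scene_id: str, masks: MaskSet, directory) -> list[Path]:
    """Write one 0/255 PNG per structure, named <scene_id>__<structure>.png."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for key, grid in masks.items():
        path = directory / f"{scene_id}__{key}.png"
        Image.fromarray((grid.astype(np.uint8)) * 255).save(path)
        paths.append(path)
    return paths


def load_masks(scene_id: str, directory) -> MaskSet:
    directory = Path(directory)
    grids = {}
    for key in STRUCTURE_KEYS:
        path = directory / f"{scene_id}__{key}.png"
        grids[key] = np.asarray(Image.open(path)) > 127
    return MaskSet(grids)


def ground_truth_to_coco(scenes: list[Scene]) -> dict:
    """COCO-style ground truth: images, annotations with [x, y, w, h]."""
    images = [
        {"id": i, "file_name": f"{s.scene_id}.png", "width": s.width, "height": s.height}
        for i, s in enumerate(scenes)
    ]
    annotations = []
    ann_id = 1
    for i, s in enumerate(scenes):
        for box, cls in s.lesions:
            annotations.append({
                "id": ann_id,
                "image_id": i,
                "category_id": CATEGORY_ID_CYST,
                "bbox": [box.x, box.y, box.w, box.h],
                "area": box.area,
                "iscrowd": 0,
                "diagnosis": cls,
            })
            ann_id += 1
    return {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": CATEGORY_ID_CYST, "name": "cyst"}],
    }


def detections_to_coco(scene_ids: list[str],
                       detections_per_scene: list[list[Detection]]) -> list[dict]:
    """COCO results format: one record per detection with a score."""
    out = []
    for image_id, (sid, dets) in enumerate(zip(scene_ids, detections_per_scene)):
        for d in dets:
            out.append({
                "image_id": image_id,
                "scene_id": sid,
                "category_id": CATEGORY_ID_CYST,
                "bbox": [d.box.x, d.box.y, d.box.w, d.box.h],
                "score": d.confidence,
            })
    return out


def coco_to_detections(records: list[dict]) -> dict[int, list[Detection]]:
    """Group COCO result records back into per-image detection lists."""
    grouped: dict[int, list[Detection]] = {}
    for r in records:
        x, y, w, h = r["bbox"]
        det = Detection(BoundingBox(int(x), int(y), int(w), int(h)), float(r["score"]))
        grouped.setdefault(int(r["image_id"]), []).append(det)
    for dets in grouped.values():
        dets.sort(key=lambda d: (-d.confidence, -d.box.area, d.box.x, d.box.y))
    return grouped


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path):
    with open(path) as fh:
        return json.load(fh)
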