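"""Decoding of raw head outputs and non-maximum suppression.

Boxes are pixel-space, 0-based, half-open ``(x1, y1, x2, y2)`` corners.
Each head cell predicts a discrete distribution over ``reg_max`` bins for
the four distances (left, top, right, bottom) from the cell center; the
expectation of that distribution, scaled by the level stride, gives the
box. Duplicates are removed by greedy class-aware NMS.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .model import REG_MAX


@dataclass
class Detection:
    category: int
    score: float
    box: tuple  # (x1, y1, x2, y2) pixels

    def __post_init__(self):
        x1, y1, x2, y2 = self.box
        if not (x2 > x1 and y2 > y1):
            raise ValueError(f"degenerate box {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


def _softmax(x: np.ndarray, axis: int) -> np.ndarray:
    e = np.exp(x - x.max(axis=axis, keepdims=True))
    return e / e.sum(axis=axis, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


def decode(
    head_outputs,
    conf_threshold: float = 0.25,
    image_size: tuple | None = None,
    strides=(8, 16, 32),
    reg_max: int = REG_MAX,
) -> list[list[Detection]]:
    """Collapse raw head maps into per-image candidate detections.

    ``head_outputs``: list of arrays (N, 4*reg_max + nc, H, W), one per level.
    Returns one list of :class:`Detection` per batch image (pre-NMS).
    """
    if not 0.0 <= conf_threshold < 1.0:
        raise ValueError("conf_threshold must lie in [0, 1)")
    arrays = [
        o if isinstance(o, np.ndarray) else np.asarray(getattr(o, "data", o))
        for o in head_outputs
    ]
    n = arrays[0].shape[0]
    nc = arrays[0].shape[1] - 4 * reg_max
    if image_size is None:
        image_size = (arrays[0].shape[3] * strides[0], arrays[0].shape[2] * strides[0])
    iw, ih = image_size
    out: list[list[Detection]] = [[] for _ in range(n)]
    proj = np.arange(reg_max, dtype=np.float32)
    for arr, stride in zip(arrays, strides):
        _, c, h, w = arr.shape
        box_logits = arr[:, : 4 * reg_max].reshape(n, 4, reg_max, h, w)
        dist = (_softmax(box_logits, axis=2) * proj[None, None, :, None, None]).sum(axis=2)
        cls = _sigmoid(arr[:, 4 * reg_max :])
        cx = (np.arange(w, dtype=np.float32) + 0.5) * stride
        cy = (np.arange(h, dtype=np.float32) + 0.5) * stride
        x1 = cx[None, None, :] - dist[:, 0] * stride
        y1 = cy[None, :, None] - dist[:, 1] * stride
        x2 = cx[None, None, :] + dist[:, 2] * stride
        y2 = cy[None, :, None] + dist[:, 3] * stride
        for i in range(n):
            scores = cls[i].reshape(nc, -1)
            keep_cat, keep_cell = np.nonzero(scores > conf_threshold)
            if keep_cell.size == 0:
                continue
            bx1 = np.clip(x1[i].reshape(-1)[keep_cell], 0, iw)
            by1 = np.clip(y1[i].reshape(-1)[keep_cell], 0, ih)
            bx2 = np.clip(x2[i].reshape(-1)[keep_cell], 0, iw)
            by2 = np.clip(y2[i].reshape(-1)[keep_cell], 0, ih)
            for cat, s, a, b_, c_, d in zip(
                keep_cat, scores[keep_cat, keep_cell], bx1, by1, bx2, by2
            ):
                if c_ > a and d > b_:
                    out[i].append(Detection(int(cat), float(s), (float(a), float(b_), float(c_), float(d))))
    return out


def encode_box(box, grid_cell, stride: int, reg_max: int = REG_MAX) -> np.ndarray:
    """Inverse of :func:`decode` for one cell: box -> one-hot-ish bin logits.

    Test helper for round-trip checks; produces logits whose softmax
    expectation reproduces the (left, top, right, bottom) distances.
    """
    gx, gy = grid_cell
    cx, cy = (gx + 0.5) * stride, (gy + 0.5) * stride
    x1, y1, x2, y2 = box
    dists = np.array([cx - x1, cy - y1, x2 - cx, y2 - cy]) / stride
    logits = np.full((4, reg_max), -20.0, dtype=np.float32)
    for k, d in enumerate(dists):
        lo = int(np.clip(np.floor(d), 0, reg_max - 1))
        hi = min(lo + 1, reg_max - 1)
        frac = float(d - lo)
        # two-hot encoding: softmax weights proportional to (1-frac, frac)
        logits[k, lo] = np.log(max(1.0 - frac, 1e-9)) + 10.0
        if hi != lo:
            logits[k, hi] = np.log(max(frac, 1e-9)) + 10.0
    return logits


def iou(a, b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes."""
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(0.0, ax2 - ax1) * max(0.0, ay2 - ay1)
    area_b = max(0.0, bx2 - bx1) * max(0.0, by2 - by1)
    if area_a == 0.0 or area_b == 0.0:
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def iou_matrix(boxes_a: np.ndarray, boxes_b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (N, 4) / (M, 4) corner-box arrays."""
    a = np.asarray(boxes_a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(boxes_b, dtype=np.float64).reshape(-1, 4)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def nms(
    detections: list[Detection],
    iou_threshold: float = 0.7,
    class_agnostic: bool = False,
) -> list[Detection]:
    """Greedy descending-score suppression; ties broken by input order."""
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    if len(detections) <= 1:
        return list(detections)
    order = sorted(
        range(len(detections)), key=lambda i: (-detections[i].score, i)
    )
    boxes = np.array([detections[i].box for i in order], dtype=np.float64)
    cats = np.array([detections[i].category for i in order])
    ious = iou_matrix(boxes, boxes)
    keep: list[int] = []
    suppressed = np.zeros(len(order), dtype=bool)
    for i in range(len(order)):
        if suppressed[i]:
            continue
        keep.append(order[i])
        overlap = ious[i] > iou_threshold
        if not class_agnostic:
            overlap &= cats == cats[i]
        overlap[: i + 1] = False
        suppressed |= overlap
    keep.sort()
    return [detections[i] for i in keep]


# ----------------------------------------------------------------- I/O utils
def detections_to_coco(detections_per_image, image_ids) -> list[dict]:
    records = []
    for img_id, dets in zip(image_ids, detections_per_image):
        for d in dets:
            x1, y1, x2, y2 = d.box
            records.append(
                {
                    "image_id": img_id,
                    "category_id": d.category,
                    "bbox": [x1, y1, x2 - x1, y2 - y1],
                    "score": d.score,
                }
            )
    return records


def write_coco_json(path, detections_per_image, image_ids):
    with open(path, "w") as fh:
        json.dump(detections_to_coco(detections_per_image, image_ids), fh, indent=1)


def write_yolo_txt(path, detections, image_size):
    """One detection per line: ``category cx cy w h score`` (normalized)."""
    iw, ih = image_size
    lines = []
    for d in detections:
        x1, y1, x2, y2 = d.box
        lines.append(
            f"{d.category} {(x1 + x2) / 2 / iw:.6f} {(y1 + y2) / 2 / ih:.6f} "
            f"{(x2 - x1) / iw:.6f} {(y2 - y1) / ih:.6f} {d.score:.6f}"
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + ("\n" if lines else ""))
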