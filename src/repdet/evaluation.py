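"""Detection metrics: greedy matching, precision/recall, AP (101-point
interpolated), mAP over IoU 0.50:0.05:0.95, confusion matrices, FPS, and
gradient-weighted class-activation heatmaps.

Conventions: AP50 is the per-category AP at IoU 0.50 averaged over
categories; mAP averages each category's AP over the ten COCO IoU
thresholds before averaging over categories. Categories without ground
truths are excluded from both means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .postprocess import Detection, iou_matrix

IOU_GRID = np.round(np.arange(0.50, 0.96, 0.05), 2)


@dataclass
class GroundTruthBox:
    category: int
    box: tuple


@dataclass
class MatchLedger:
    """Greedy detection/ground-truth assignment at one IoU threshold."""

    iou_threshold: float
    # one entry per detection, in score order: (detection, gt_index or None)
    matches: list = field(default_factory=list)
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def num_detections(self) -> int:
        return self.tp + self.fp


def match_detections(
    detections: list[Detection],
    ground_truths: list[GroundTruthBox],
    iou_match_threshold: float = 0.5,
) -> MatchLedger:
    """Match one image's detections against its ground truths.

    Detections are processed in descending score order; each is assigned
    the highest-IoU unmatched same-category ground truth with IoU >= the
    threshold. Unmatched ground truths count as false negatives.
    """
    ledger = MatchLedger(iou_match_threshold)
    order = sorted(range(len(detections)), key=lambda i: (-detections[i].score, i))
    gt_used = [False] * len(ground_truths)
    if ground_truths and detections:
        gt_boxes = np.array([g.box for g in ground_truths], dtype=np.float64)
        det_boxes = np.array([detections[i].box for i in order], dtype=np.float64)
        ious = iou_matrix(det_boxes, gt_boxes)
    for rank, di in enumerate(order):
        det = detections[di]
        best_j, best_iou = None, iou_match_threshold
        for j, gt in enumerate(ground_truths):
            if gt_used[j] or gt.category != det.category:
                continue
            v = ious[rank, j]
            if v >= best_iou and (best_j is None or v > best_iou):
                best_j, best_iou = j, v
        if best_j is not None:
            gt_used[best_j] = True
            ledger.matches.append((det, best_j))
            ledger.tp += 1
        else:
            ledger.matches.append((det, None))
            ledger.fp += 1
    ledger.fn = gt_used.count(False)
    return ledger


def precision(ledger: MatchLedger) -> float:
    denom = ledger.tp + ledger.fp
    return ledger.tp / denom if denom else 0.0


def recall(ledger: MatchLedger) -> float:
    denom = ledger.tp + ledger.fn
    return ledger.tp / denom if denom else 0.0


def average_precision(
    scores: np.ndarray, is_tp: np.ndarray, num_gt: int
) -> float:
    """101-point interpolated AP from a pooled, scored TP/FP sequence."""
    if num_gt == 0:
        return float("nan")
    if scores.size == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp_cum = np.cumsum(is_tp[order])
    fp_cum = np.cumsum(~is_tp[order])
    rec = tp_cum / num_gt
    prec = tp_cum / (tp_cum + fp_cum)
    # precision envelope, then sample at 101 recall points
    prec_env = np.maximum.accumulate(prec[::-1])[::-1]
    recall_points = np.linspace(0, 1, 101)
    idx = np.searchsorted(rec, recall_points, side="left")
    sampled = np.where(idx < rec.size, prec_env[np.minimum(idx, rec.size - 1)], 0.0)
    return float(sampled.mean())


@dataclass
class EvalResult:
    ap50_per_category: dict
    ap_per_category: dict  # averaged over the IoU grid
    ap50: float
    map: float
    precision: float
    recall: float

    def to_dict(self) -> dict:
        return {
            "AP50": self.ap50,
            "mAP": self.map,
            "precision": self.precision,
            "recall": self.recall,
            "AP50_per_category": {str(k): v for k, v in self.ap50_per_category.items()},
            "AP_per_category": {str(k): v for k, v in self.ap_per_category.items()},
        }


def _category_ap(dets_per_image, gts_per_image, category, iou_thr):
    scores, flags = [], []
    num_gt = 0
    for dets, gts in zip(dets_per_image, gts_per_image):
        cat_dets = [d for d in dets if d.category == category]
        cat_gts = [g for g in gts if g.category == category]
        num_gt += len(cat_gts)
        ledger = match_detections(cat_dets, cat_gts, iou_thr)
        for det, gt_j in ledger.matches:
            scores.append(det.score)
            flags.append(gt_j is not None)
    return average_precision(np.array(scores), np.array(flags, dtype=bool), num_gt), num_gt


def map_metric(
    dets_per_image: list[list[Detection]],
    gts_per_image: list[list[GroundTruthBox]],
    num_categories: int,
    iou_grid=IOU_GRID,
    pr_iou: float = 0.5,
) -> EvalResult:
    """Dataset-level AP50 / mAP plus pooled precision and recall at pr_iou."""
    ap50_per_cat, ap_per_cat = {}, {}
    any_gt = False
    for cat in range(num_categories):
        aps = []
        for thr in iou_grid:
            ap, num_gt = _category_ap(dets_per_image, gts_per_image, cat, thr)
            aps.append(ap)
        if num_gt == 0:
            continue
        any_gt = True
        ap50_per_cat[cat] = aps[0] if iou_grid[0] == 0.5 else _category_ap(
            dets_per_image, gts_per_image, cat, 0.5
        )[0]
        ap_per_cat[cat] = float(np.mean(aps))
    if not any_gt:
        raise ValueError("no annotated categories: mAP undefined")
    tp = fp = fn = 0
    for dets, gts in zip(dets_per_image, gts_per_image):
        ledger = match_detections(dets, gts, pr_iou)
        tp += ledger.tp
        fp += ledger.fp
        fn += ledger.fn
    return EvalResult(
        ap50_per_category=ap50_per_cat,
        ap_per_category=ap_per_cat,
        ap50=float(np.mean(list(ap50_per_cat.values()))),
        map=float(np.mean(list(ap_per_cat.values()))),
        precision=tp / (tp + fp) if tp + fp else 0.0,
        recall=tp / (tp + fn) if tp + fn else 0.0,
    )


def fps(preprocess_time: float, inference_time: float, postprocess_time: float) -> float:
    """Frames per second from mean per-image stage times (seconds)."""
    total = preprocess_time + inference_time + postprocess_time
    if total <= 0:
        raise ValueError("total per-image time must be positive")
    return 1.0 / total


def confusion_matrix(
    dets_per_image,
    gts_per_image,
    num_categories: int,
    iou_threshold: float = 0.5,
) -> np.ndarray:
    """(nc+1) x (nc+1) table: rows predicted, columns actual; index nc is
    background (unmatched detections / missed ground truths).

    Boxes are matched class-agnostically so that classification confusions
    between categories are visible; column sums over actual categories
    equal ground-truth counts.
    """
    nc = num_categories
    table = np.zeros((nc + 1, nc + 1), dtype=np.int64)
    for dets, gts in zip(dets_per_image, gts_per_image):
        order = sorted(range(len(dets)), key=lambda i: (-dets[i].score, i))
        gt_used = [False] * len(gts)
        if dets and gts:
            ious = iou_matrix(
                np.array([dets[i].box for i in order]),
                np.array([g.box for g in gts]),
            )
        for rank, di in enumerate(order):
            det = dets[di]
            best_j, best_v = None, iou_threshold
            for j, g in enumerate(gts):
                if gt_used[j]:
                    continue
                if ious[rank, j] >= best_v and (best_j is None or ious[rank, j] > best_v):
                    best_j, best_v = j, ious[rank, j]
            if best_j is None:
                table[det.category, nc] += 1  # spurious detection
            else:
                gt_used[best_j] = True
                table[det.category, gts[best_j].category] += 1
        for j, g in enumerate(gts):
            if not gt_used[j]:
                table[nc, g.category] += 1  # missed ground truth
    return table


# ------------------------------------------------------------------ heatmaps
def _bilinear_resize(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = img.shape
    if (h, w) == (out_h, out_w):
        return img
    ys = (np.arange(out_h) + 0.5) * h / out_h - 0.5
    xs = (np.arange(out_w) + 0.5) * w / out_w - 0.5
    y0 = np.clip(np.floor(ys).astype(int), 0, h - 1)
    x0 = np.clip(np.floor(xs).astype(int), 0, w - 1)
    y1 = np.clip(y0 + 1, 0, h - 1)
    x1 = np.clip(x0 + 1, 0, w - 1)
    wy = np.clip(ys - y0, 0, 1)[:, None]
    wx = np.clip(xs - x0, 0, 1)[None, :]
    return (
        img[np.ix_(y0, x0)] * (1 - wy) * (1 - wx)
        + img[np.ix_(y1, x0)] * wy * (1 - wx)
        + img[np.ix_(y0, x1)] * (1 - wy) * wx
        + img[np.ix_(y1, x1)] * wy * wx
    )


def activation_heatmap(model, image: np.ndarray, block: int | str) -> np.ndarray:
    """Gradient-weighted class-activation map for one graph block.

    ``image``: (3, H, W) float array. ``block``: graph layer index or a
    name from ``model.named_blocks``. Returns an (H, W) map in [0, 1].
    """
    from .model import REG_MAX  # local import to avoid cycle at module load

    if isinstance(block, str):
        try:
            block = model.named_blocks[block]
        except KeyError:
            raise KeyError(
                f"unknown block {block!r}; available: {sorted(model.named_blocks)}"
            ) from None
    x = np.asarray(image, dtype=np.float32)[None]
    model.zero_grad()
    heads, act = model.capture_forward(x, block)
    nc = heads[0].shape[1] - 4 * REG_MAX
    score = sum(h[:, 4 * REG_MAX :].max(axis=1).sum() for h in heads)
    score.backward()
    grads = act.grad
    if grads is None:
        raise RuntimeError("no gradient reached the requested block")
    weights = grads.mean(axis=(2, 3), keepdims=True)  # GAP of gradients
    cam = np.maximum((weights * act.data).sum(axis=1)[0], 0.0)
    lo, hi = cam.min(), cam.max()
    cam = (cam - lo) / (hi - lo) if hi > lo else np.zeros_like(cam)
    return _bilinear_resize(cam, x.shape[2], x.shape[3])


def render_heatmap_overlay(image: np.ndarray, cam: np.ndarray, path):
    """Save image + jet-colored activation overlay as PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 3 and img.shape[0] in (1, 3):
        img = img.transpose(1, 2, 0)
    if img.max() > 1.5:
        img = img / 255.0
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img.squeeze(), cmap="gray" if img.ndim == 2 or img.shape[-1] == 1 else None)
    ax.imshow(cam, cmap="jet", alpha=0.4)
    ax.axis("off")
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
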