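"""Desk-scale training: task-aligned assignment, BCE + CIoU + DFL loss,
AdamW with linear learning-rate decay.

The loop is deliberately small — it exists to demonstrate that the
detector learns on synthetic phantoms on one CPU, not to reproduce
GPU-scale training runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .augment import AugmentConfig, augment_record
from .evaluation import GroundTruthBox, map_metric
from .model import REG_MAX, Detector
from .phantom import PhantomRecord, to_model_input
from .postprocess import decode, iou_matrix, nms


# ------------------------------------------------------------ target assigner
def task_aligned_assign(
    cls_prob: np.ndarray,   # (A, nc) sigmoid scores (detached)
    pred_boxes: np.ndarray, # (A, 4) decoded boxes (detached)
    anchors: np.ndarray,    # (A, 2) cell centers, pixels
    gt_boxes: np.ndarray,   # (G, 4)
    gt_cats: np.ndarray,    # (G,)
    topk: int = 10,
    alpha: float = 0.5,
    beta: float = 6.0,
):
    """Select positive anchors per ground truth by the alignment metric
    score^alpha * IoU^beta among anchors whose center lies inside the box."""
    num_anchors = anchors.shape[0]
    fg = np.zeros(num_anchors, dtype=bool)
    assigned_gt = np.full(num_anchors, -1, dtype=int)
    target_scores = np.zeros(num_anchors, dtype=np.float64)
    if len(gt_boxes) == 0:
        return fg, assigned_gt, target_scores
    inside = (
        (anchors[:, 0] >= gt_boxes[:, None, 0])
        & (anchors[:, 0] <= gt_boxes[:, None, 2])
        & (anchors[:, 1] >= gt_boxes[:, None, 1])
        & (anchors[:, 1] <= gt_boxes[:, None, 3])
    )  # (G, A)
    ious = iou_matrix(gt_boxes, pred_boxes)  # (G, A)
    scores = cls_prob[:, gt_cats].T  # (G, A)
    align = (scores**alpha) * (ious**beta) * inside
    # top-k candidates per gt
    cand = np.zeros_like(inside)
    for g in range(len(gt_boxes)):
        k = min(topk, int(inside[g].sum()))
        if k == 0:
            continue
        top = np.argpartition(-align[g], k - 1)[:k]
        cand[g, top] = align[g, top] > 0
    # resolve anchors claimed by several gts: keep the highest IoU one
    claimed = cand.sum(axis=0)
    multi = claimed > 1
    if multi.any():
        best_gt = np.argmax(np.where(cand, ious, -1.0), axis=0)
        cand[:, multi] = False
        cand[best_gt[multi], multi] = True
    for g in range(len(gt_boxes)):
        idx = np.nonzero(cand[g])[0]
        if idx.size == 0:
            continue
        fg[idx] = True
        assigned_gt[idx] = g
        amax = align[g, idx].max()
        imax = ious[g, idx].max()
        if amax > 0:
            target_scores[idx] = align[g, idx] / amax * imax
        else:
            target_scores[idx] = ious[g, idx]
    return fg, assigned_gt, target_scores


# ------------------------------------------------------------------ the loss
def _flatten_heads(head_outputs, strides=(8, 16, 32)):
    """Per-level maps -> (N, A, C) tensor plus anchor centers and strides."""
    flats, centers, strs = [], [], []
    for out, s in zip(head_outputs, strides):
        n, c, h, w = out.shape
        flats.append(out.reshape(n, c, h * w).transpose(0, 2, 1))
        gx, gy = np.meshgrid(np.arange(w), np.arange(h))
        centers.append(
            np.stack([(gx.ravel() + 0.5) * s, (gy.ravel() + 0.5) * s], axis=1)
        )
        strs.append(np.full(h * w, s, dtype=np.float64))
    return (
        ag.concat(flats, axis=1),
        np.concatenate(centers, axis=0),
        np.concatenate(strs, axis=0),
    )


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    t = Tensor(targets.astype(np.float32))
    return (
        logits.clip(0, None) - logits * t + (1.0 + (-logits.abs()).exp()).log()
    )


def _ciou_loss(pred: Tensor, gt: np.ndarray) -> Tensor:
    """Complete-IoU loss between (K, 4) predicted and ground-truth corners."""
    g = Tensor(gt.astype(np.float32))
    ix1 = pred[:, 0].maximum(g[:, 0])
    iy1 = pred[:, 1].maximum(g[:, 1])
    ix2 = pred[:, 2].minimum(g[:, 2])
    iy2 = pred[:, 3].minimum(g[:, 3])
    inter = (ix2 - ix1).clip(0, None) * (iy2 - iy1).clip(0, None)
    pw = (pred[:, 2] - pred[:, 0]).clip(1e-6, None)
    ph = (pred[:, 3] - pred[:, 1]).clip(1e-6, None)
    gw = g[:, 2] - g[:, 0]
    gh = g[:, 3] - g[:, 1]
    union = pw * ph + gw * gh - inter
    iou_t = inter / (union + 1e-7)
    # enclosing-box diagonal and center distance
    cw = pred[:, 2].maximum(g[:, 2]) - pred[:, 0].minimum(g[:, 0])
    ch = pred[:, 3].maximum(g[:, 3]) - pred[:, 1].minimum(g[:, 1])
    c2 = cw * cw + ch * ch + 1e-7
    dx = (pred[:, 0] + pred[:, 2] - g[:, 0] - g[:, 2]) * 0.5
    dy = (pred[:, 1] + pred[:, 3] - g[:, 1] - g[:, 3]) * 0.5
    rho2 = dx * dx + dy * dy
    v = (4.0 / np.pi**2) * ((gw / gh).atan() - (pw / ph).atan()) ** 2
    with np.errstate(all="ignore"):
        alpha = v.data / (1.0 - iou_t.data + v.data + 1e-7)  # detached, as usual
    return 1.0 - iou_t + rho2 / c2 + v * Tensor(alpha.astype(np.float32))


@dataclass
class DetectionLoss:
    num_categories: int
    reg_max: int = REG_MAX
    box_weight: float = 7.5
    cls_weight: float = 0.5
    dfl_weight: float = 1.5
    strides: tuple = (8, 16, 32)

    def __call__(self, head_outputs, gt_per_image):
        flat, centers, strs = _flatten_heads(head_outputs, self.strides)
        n, num_anchors, _ = flat.shape
        nc = self.num_categories
        rm = self.reg_max
        box_logits = flat[:, :, : 4 * rm]
        cls_logits = flat[:, :, 4 * rm :]
        dist_soft = box_logits.reshape(n, num_anchors, 4, rm).softmax(axis=3)
        proj = Tensor(np.arange(rm, dtype=np.float32).reshape(1, 1, 1, rm))
        dist = (dist_soft * proj).sum(axis=3)  # (N, A, 4) in stride units
        sv = Tensor(strs.astype(np.float32).reshape(1, -1, 1))
        cx = Tensor(centers[:, 0].astype(np.float32).reshape(1, -1))
        cy = Tensor(centers[:, 1].astype(np.float32).reshape(1, -1))
        px1 = cx - dist[:, :, 0] * sv[:, :, 0]
        py1 = cy - dist[:, :, 1] * sv[:, :, 0]
        px2 = cx + dist[:, :, 2] * sv[:, :, 0]
        py2 = cy + dist[:, :, 3] * sv[:, :, 0]
        pred_boxes = ag.stack([px1, py1, px2, py2], axis=2)  # (N, A, 4)

        total_cls = Tensor(np.float32(0.0))
        total_box = Tensor(np.float32(0.0))
        total_dfl = Tensor(np.float32(0.0))
        total_norm = 0.0
        cls_prob_all = 1.0 / (1.0 + np.exp(-cls_logits.data))
        for i in range(n):
            gts = gt_per_image[i]
            gt_boxes = np.asarray([g.box for g in gts], dtype=np.float64).reshape(-1, 4)
            gt_cats = np.asarray([g.category for g in gts], dtype=int)
            fg, agt, tscore = task_aligned_assign(
                cls_prob_all[i], pred_boxes.data[i], centers, gt_boxes, gt_cats
            )
            targets = np.zeros((num_anchors, nc), dtype=np.float32)
            if fg.any():
                targets[fg, gt_cats[agt[fg]]] = tscore[fg]
            norm = max(float(tscore.sum()), 1.0)
            total_norm += norm
            total_cls = total_cls + _bce_with_logits(cls_logits[i], targets).sum() * (
                1.0 / norm
            )
            if not fg.any():
                continue
            idx = np.nonzero(fg)[0]
            w = Tensor((tscore[idx] / norm).astype(np.float32))
            pb = pred_boxes[i][idx]
            gb = gt_boxes[agt[idx]]
            total_box = total_box + (_ciou_loss(pb, gb) * w).sum()
            # DFL: two-hot cross entropy on the true stride-normalized distances
            tx = np.stack(
                [
                    (centers[idx, 0] - gb[:, 0]),
                    (centers[idx, 1] - gb[:, 1]),
                    (gb[:, 2] - centers[idx, 0]),
                    (gb[:, 3] - centers[idx, 1]),
                ],
                axis=1,
            ) / strs[idx][:, None]
            tx = np.clip(tx, 0, rm - 1 - 0.01)
            lo = np.floor(tx).astype(int)
            hi = lo + 1
            wl = (hi - tx).astype(np.float32)
            wh = (tx - lo).astype(np.float32)
            logp = box_logits[i][idx].reshape(len(idx), 4, rm).log_softmax(axis=2)
            a0 = np.arange(len(idx))[:, None]
            a1 = np.arange(4)[None, :]
            ce = -(logp[a0, a1, lo] * Tensor(wl) + logp[a0, a1, hi] * Tensor(wh))
            total_dfl = total_dfl + (ce.mean(axis=1) * w).sum()
        scale = 1.0 / n
        loss = (
            total_cls * (self.cls_weight * scale)
            + total_box * (self.box_weight * scale)
            + total_dfl * (self.dfl_weight * scale)
        )
        parts = {
            "cls": float(total_cls.data) * scale,
            "box": float(total_box.data) * scale,
            "dfl": float(total_dfl.data) * scale,
        }
        return loss, parts


# ----------------------------------------------------------------- optimizer
class AdamW:
    def __init__(self, params, lr=0.01, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0005):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            if p.data.ndim > 1 and self.wd:  # decay conv/linear weights only
                p.data *= 1 - self.lr * self.wd
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


@dataclass
class TrainConfig:
    epochs: int = 100          # published recipe default; desk runs use steps
    steps: int | None = None   # overrides epochs when set
    batch_size: int = 16
    lr0: float = 0.01
    lrf: float = 0.01          # final lr fraction (linear decay)
    weight_decay: float = 0.0005
    warmup_steps: int = 20
    imgsz: int = 640
    seed: int = 0
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    use_augment: bool = True


def _resize_record(image: np.ndarray, labels: np.ndarray, size: int):
    h, w = image.shape[:2]
    if (h, w) == (size, size):
        return image, labels
    ys = (np.arange(size) * h // size).clip(0, h - 1)
    xs = (np.arange(size) * w // size).clip(0, w - 1)
    img = image[np.ix_(ys, xs)]
    if labels is None or len(labels) == 0:
        return img, np.zeros((0, 5))
    lb = np.asarray(labels, dtype=np.float64).copy()
    lb[:, [1, 3]] *= size / w
    lb[:, [2, 4]] *= size / h
    return img, lb


def make_batch(records: list[PhantomRecord], cfg: TrainConfig, rng, augmenting: bool):
    """Sample, augment and tensorize one batch; returns (X, gt lists)."""
    xs, gts = [], []
    for _ in range(cfg.batch_size):
        if augmenting and cfg.use_augment:
            picks = [records[rng.integers(len(records))] for _ in range(4)]
            img, labels = augment_record(
                [(p.image, p.labels) for p in picks], cfg.augment, rng, picks[0].image.shape[0]
            )
        else:
            p = records[rng.integers(len(records))]
            img, labels = p.image, p.labels
        img, labels = _resize_record(img, labels, cfg.imgsz)
        xs.append(to_model_input(img))
        gts.append(
            [GroundTruthBox(int(c), (x1, y1, x2, y2)) for c, x1, y1, x2, y2 in labels]
        )
    return np.stack(xs), gts


def train(model: Detector, records: list[PhantomRecord], cfg: TrainConfig, log=None):
    """Run the training loop; returns the per-step loss history."""
    rng = np.random.default_rng(cfg.seed)
    loss_fn = DetectionLoss(model.config.num_categories)
    opt = AdamW(model.parameters(), lr=cfg.lr0, weight_decay=cfg.weight_decay)
    steps = cfg.steps if cfg.steps is not None else cfg.epochs * max(
        1, len(records) // cfg.batch_size
    )
    history = []
    model.train()
    for step in range(steps):
        frac = step / max(steps - 1, 1)
        lr = cfg.lr0 * (1.0 - frac * (1.0 - cfg.lrf))  # linear decay to lr0*lrf
        if step < cfg.warmup_steps:
            lr *= (step + 1) / cfg.warmup_steps
        opt.lr = lr
        x, gts = make_batch(records, cfg, rng, augmenting=True)
        outs = model(x)
        loss, parts = loss_fn(outs, gts)
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append({"step": step, "lr": lr, "loss": float(loss.data), **parts})
        if log and (step % 10 == 0 or step == steps - 1):
            log(f"step {step:4d} lr {lr:.4f} loss {float(loss.data):.3f} {parts}")
    model.eval()
    return history


def evaluate(
    model: Detector,
    records: list[PhantomRecord],
    imgsz: int = 640,
    conf_threshold: float = 0.001,
    nms_iou: float = 0.7,
    batch_size: int = 8,
):
    """No-augmentation evaluation path: decode + NMS + AP metrics."""
    model.eval()
    dets_all, gts_all = [], []
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        xs, gts = [], []
        for r in chunk:
            img, labels = _resize_record(r.image, r.labels, imgsz)
            xs.append(to_model_input(img))
            gts.append(
                [GroundTruthBox(int(c), (x1, y1, x2, y2)) for c, x1, y1, x2, y2 in labels]
            )
        with ag.no_grad():
            outs = model(np.stack(xs))
        decoded = decode(outs, conf_threshold, image_size=(imgsz, imgsz))
        for dets in decoded:
            dets_all.append(nms(dets, nms_iou))
        gts_all.extend(gts)
    return map_metric(dets_all, gts_all, model.config.num_categories)
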