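"""Training-time augmentation: mosaic stitching, HSV jitter, random
affine (translate/scale/rotate) and horizontal flip, with label remapping.

Defaults follow the training recipe: HSV gains (0.015, 0.7, 0.4),
translate 0.1, scale gain 0.5, flip probability 0.5. Images are HWC
uint8; labels are (N, 5) float arrays ``[category, x1, y1, x2, y2]`` in
pixel coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MIN_BOX_SIDE = 2.0  # px; smaller post-clip boxes are dropped


@dataclass
class AugmentConfig:
    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    translate: float = 0.1
    scale_gain: float = 0.5
    rotate_deg: float = 0.0
    fliplr_prob: float = 0.5
    mosaic_prob: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("fliplr_prob", "mosaic_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("hsv_h", "hsv_s", "hsv_v", "translate", "scale_gain"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _clip_boxes(labels: np.ndarray, w: float, h: float) -> np.ndarray:
    if labels.size == 0:
        return labels.reshape(0, 5)
    out = labels.copy()
    out[:, 1] = np.clip(out[:, 1], 0, w)
    out[:, 3] = np.clip(out[:, 3], 0, w)
    out[:, 2] = np.clip(out[:, 2], 0, h)
    out[:, 4] = np.clip(out[:, 4], 0, h)
    keep = (out[:, 3] - out[:, 1] >= MIN_BOX_SIDE) & (out[:, 4] - out[:, 2] >= MIN_BOX_SIDE)
    return out[keep]


def mosaic(records, output_size: int, rng: np.random.Generator):
    """Stitch four (image, labels) records around a random center.

    Each source image is placed into one quadrant, cropped to fit; labels
    move to mosaic coordinates, get clipped and degenerate boxes dropped.
    """
    if len(records) != 4:
        raise ValueError(f"mosaic needs exactly 4 records, got {len(records)}")
    s = output_size
    canvas = np.zeros(
        (s, s) + (() if records[0][0].ndim == 2 else (records[0][0].shape[2],)),
        dtype=records[0][0].dtype,
    )
    # center sampled uniformly within the central half of the canvas
    cx = int(rng.uniform(s // 4, 3 * s // 4))
    cy = int(rng.uniform(s // 4, 3 * s // 4))
    out_labels = []
    regions = [  # (x1, y1, x2, y2) of each quadrant on the canvas
        (0, 0, cx, cy),
        (cx, 0, s, cy),
        (0, cy, cx, s),
        (cx, cy, s, s),
    ]
    for (img, labels), (x1, y1, x2, y2) in zip(records, regions):
        qw, qh = x2 - x1, y2 - y1
        if qw <= 0 or qh <= 0:
            continue
        ih, iw = img.shape[:2]
        # left/top quadrants take the right/bottom crop of their source so
        # content always meets the mosaic center
        sx1 = max(iw - qw, 0) if x2 == cx else 0
        sy1 = max(ih - qh, 0) if y2 == cy else 0
        crop = img[sy1 : sy1 + qh, sx1 : sx1 + qw]
        canvas[y1 : y1 + crop.shape[0], x1 : x1 + crop.shape[1]] = crop
        if labels is not None and len(labels):
            lb = np.asarray(labels, dtype=np.float64).copy()
            lb[:, [1, 3]] += x1 - sx1
            lb[:, [2, 4]] += y1 - sy1
            # restrict to this quadrant before the global clip
            lb[:, 1] = np.clip(lb[:, 1], x1, x2)
            lb[:, 3] = np.clip(lb[:, 3], x1, x2)
            lb[:, 2] = np.clip(lb[:, 2], y1, y2)
            lb[:, 4] = np.clip(lb[:, 4], y1, y2)
            out_labels.append(lb)
    labels = (
        np.concatenate(out_labels, axis=0) if out_labels else np.zeros((0, 5))
    )
    return canvas, _clip_boxes(labels, s, s)


def _rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    maxc = rgb.max(axis=-1)
    minc = rgb.min(axis=-1)
    v = maxc
    delta = maxc - minc
    s = np.where(maxc > 0, delta / np.maximum(maxc, 1e-12), 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        rc = (maxc - r) / np.maximum(delta, 1e-12)
        gc = (maxc - g) / np.maximum(delta, 1e-12)
        bc = (maxc - b) / np.maximum(delta, 1e-12)
    h = np.select(
        [maxc == r, maxc == g], [bc - gc, 2.0 + rc - bc], default=4.0 + gc - rc
    )
    h = np.where(delta > 0, (h / 6.0) % 1.0, 0.0)
    return np.stack([h, s, v], axis=-1)


def _hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    i = np.floor(h * 6.0).astype(int) % 6
    f = h * 6.0 - np.floor(h * 6.0)
    p = v * (1 - s)
    q = v * (1 - s * f)
    t = v * (1 - s * (1 - f))
    r = np.select([i == 0, i == 1, i == 2, i == 3, i == 4], [v, q, p, p, t], default=v)
    g = np.select([i == 0, i == 1, i == 2, i == 3, i == 4], [t, v, v, q, p], default=p)
    b = np.select([i == 0, i == 1, i == 2, i == 3, i == 4], [p, p, t, v, v], default=q)
    return np.stack([r, g, b], axis=-1)


def hsv_jitter(image: np.ndarray, gains=(0.015, 0.7, 0.4), rng: np.random.Generator = None):
    """Random multiplicative H/S/V jitter within +-gain; 8-bit in and out.

    Single-channel inputs are processed through a replicated 3-channel view
    (value jitter is then the only effective component).
    """
    if image.dtype != np.uint8:
        raise ValueError("hsv_jitter expects an 8-bit image")
    rng = rng or np.random.default_rng()
    factors = rng.uniform(-1, 1, 3) * np.asarray(gains) + 1.0
    if all(g == 0 for g in gains):
        return image.copy()
    gray = image.ndim == 2 or (image.ndim == 3 and image.shape[2] == 1)
    rgb = image.reshape(image.shape[0], image.shape[1], -1)
    if gray:
        rgb = np.repeat(rgb[:, :, :1], 3, axis=2)
    hsv = _rgb_to_hsv(rgb.astype(np.float64) / 255.0)
    hsv[..., 0] = (hsv[..., 0] * factors[0]) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * factors[1], 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * factors[2], 0, 1)
    out = np.clip(np.round(_hsv_to_rgb(hsv) * 255.0), 0, 255).astype(np.uint8)
    if gray:
        out = out[:, :, 0].reshape(image.shape)
    return out


def random_affine(
    image: np.ndarray,
    labels: np.ndarray,
    translate: float = 0.1,
    scale_gain: float = 0.5,
    rotate_deg: float = 0.0,
    rng: np.random.Generator = None,
):
    """One sampled affine (scale, rotate, translate) applied to image+boxes.

    Boxes map to the axis-aligned hull of their four transformed corners,
    then get clipped; degenerate results are removed.
    """
    rng = rng or np.random.default_rng()
    h, w = image.shape[:2]
    scale = 1.0 + rng.uniform(-scale_gain, scale_gain)
    angle = rng.uniform(-rotate_deg, rotate_deg)
    tx = rng.uniform(-translate, translate) * w
    ty = rng.uniform(-translate, translate) * h
    theta = np.deg2rad(angle)
    cos, sin = np.cos(theta) * scale, np.sin(theta) * scale
    cx, cy = w / 2.0, h / 2.0
    # rotate+scale about the image center, then translate
    m = np.array(
        [
            [cos, -sin, cx - cos * cx + sin * cy + tx],
            [sin, cos, cy - sin * cx - cos * cy + ty],
        ]
    )
    out_img = _warp_affine(image, m, (h, w))
    if labels is None or len(labels) == 0:
        return out_img, np.zeros((0, 5))
    lb = np.asarray(labels, dtype=np.float64)
    corners = np.stack(
        [
            lb[:, [1, 2]], lb[:, [3, 2]], lb[:, [1, 4]], lb[:, [3, 4]],
        ],
        axis=1,
    )  # (N, 4, 2)
    ones = np.ones((*corners.shape[:2], 1))
    warped = np.concatenate([corners, ones], axis=2) @ m.T  # (N, 4, 2)
    new = np.column_stack(
        [
            lb[:, 0],
            warped[:, :, 0].min(axis=1),
            warped[:, :, 1].min(axis=1),
            warped[:, :, 0].max(axis=1),
            warped[:, :, 1].max(axis=1),
        ]
    )
    return out_img, _clip_boxes(new, w, h)


def _warp_affine(image: np.ndarray, m: np.ndarray, out_shape) -> np.ndarray:
    """Nearest-neighbor inverse warp (adequate for phantom-scale work)."""
    h, w = out_shape
    inv = np.linalg.inv(np.vstack([m, [0, 0, 1]]))[:2]
    ys, xs = np.mgrid[0:h, 0:w]
    coords = np.stack([xs.ravel(), ys.ravel(), np.ones(h * w)])
    src = inv @ coords
    sx = np.round(src[0]).astype(int)
    sy = np.round(src[1]).astype(int)
    valid = (sx >= 0) & (sx < image.shape[1]) & (sy >= 0) & (sy < image.shape[0])
    out = np.zeros((h, w) + image.shape[2:], dtype=image.dtype)
    out.reshape(h * w, *image.shape[2:])[valid] = image[sy[valid], sx[valid]]
    return out


def fliplr(
    image: np.ndarray,
    labels: np.ndarray,
    prob: float = 0.5,
    rng: np.random.Generator = None,
    force: bool | None = None,
):
    """Mirror horizontally with the given probability; x1' = W - x2."""
    rng = rng or np.random.default_rng()
    do = force if force is not None else bool(rng.uniform() < prob)
    if not do:
        return image, (np.zeros((0, 5)) if labels is None else np.asarray(labels, dtype=np.float64))
    w = image.shape[1]
    out_img = image[:, ::-1].copy()
    if labels is None or len(labels) == 0:
        return out_img, np.zeros((0, 5))
    lb = np.asarray(labels, dtype=np.float64).copy()
    x1 = w - lb[:, 3]
    x2 = w - lb[:, 1]
    lb[:, 1], lb[:, 3] = x1, x2
    return out_img, lb


def augment_record(records, config: AugmentConfig, rng: np.random.Generator, output_size: int):
    """Full train-time stack for one sample (4 candidate source records)."""
    if rng.uniform() < config.mosaic_prob:
        img, labels = mosaic(records[:4], output_size, rng)
    else:
        img, labels = records[0]
        img = img.copy()
        labels = np.asarray(labels, dtype=np.float64).copy() if labels is not None else np.zeros((0, 5))
    img = hsv_jitter(img, (config.hsv_h, config.hsv_s, config.hsv_v), rng)
    img, labels = random_affine(
        img, labels, config.translate, config.scale_gain, config.rotate_deg, rng
    )
    img, labels = fliplr(img, labels, config.fliplr_prob, rng)
    return img, labels
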