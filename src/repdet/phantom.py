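"""Synthetic grayscale lesion phantoms with bounding-box annotations.

Each phantom is a skull-like ellipse with smooth internal texture and
Gaussian noise; lesion categories differ by position prior, eccentricity
and intensity polarity so that a detector can separate them. Category 3
("notumor") carries no lesion and no box. Generation is fully determined
by integer seeds, so datasets are reproducible and need not be shipped.

Label formats: YOLO txt (normalized center-size), labelme-style JSON and
COCO-style JSON, all round-tripping within 0.5 px.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

CATEGORIES = ("glioma", "meningioma", "pituitary", "notumor")
NOTUMOR = 3
IMAGE_SIZE = 640

# (center-x frac, center-y frac, axis frac, eccentricity, bright?) priors
_CATEGORY_SIGNATURES = {
    0: dict(cx=0.38, cy=0.40, ax=0.085, ecc=0.55, bright=True, irregular=True),
    1: dict(cx=0.62, cy=0.30, ax=0.075, ecc=0.35, bright=True, irregular=False),
    2: dict(cx=0.50, cy=0.66, ax=0.060, ecc=0.25, bright=False, irregular=False),
}


@dataclass
class PhantomRecord:
    image: np.ndarray  # (H, W) uint8
    category: int
    boxes: np.ndarray  # (0 or 1, 4) pixel corners
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        """(N, 5) [category, x1, y1, x2, y2] array for the augment stack."""
        if len(self.boxes) == 0:
            return np.zeros((0, 5))
        return np.column_stack([[self.category] * len(self.boxes), self.boxes])


def generate_phantom(seed: int, category: int, difficulty: float = 0.0, size: int = IMAGE_SIZE) -> PhantomRecord:
    """Deterministic single-phantom generator.

    ``difficulty`` in [0, 1] lowers lesion contrast and raises noise.
    """
    if category not in range(len(CATEGORIES)):
        raise ValueError(f"unknown category {category}")
    if not 0.0 <= difficulty <= 1.0:
        raise ValueError("difficulty must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    h = w = size
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = w / 2, h / 2
    skull_a = w * rng.uniform(0.33, 0.38)
    skull_b = h * rng.uniform(0.40, 0.45)
    d2 = ((xx - cx) / skull_a) ** 2 + ((yy - cy) / skull_b) ** 2
    brain = d2 <= 1.0

    # smooth low-frequency texture from a few random cosine modes
    tex = np.zeros((h, w))
    for _ in range(4):
        fx, fy = rng.uniform(1, 4, 2)
        ph = rng.uniform(0, 2 * math.pi, 2)
        tex += rng.uniform(0.2, 0.5) * np.cos(2 * math.pi * fx * xx / w + ph[0]) * np.cos(
            2 * math.pi * fy * yy / h + ph[1]
        )
    tex = (tex - tex.min()) / (tex.max() - tex.min() + 1e-12)
    img = np.where(brain, 70 + 60 * tex, 8.0)
    img += np.where(d2 <= 1.0, 0.0, 0.0) + np.where((d2 > 0.92) & (d2 <= 1.0), 60.0, 0.0)

    boxes = np.zeros((0, 4))
    meta = {"seed": int(seed), "category": CATEGORIES[category], "difficulty": difficulty}
    if category != NOTUMOR:
        sig = _CATEGORY_SIGNATURES[category]
        jitter = 0.05
        lcx = w * (sig["cx"] + rng.uniform(-jitter, jitter))
        lcy = h * (sig["cy"] + rng.uniform(-jitter, jitter))
        a = w * sig["ax"] * rng.uniform(0.85, 1.25)
        b = a * (1.0 - sig["ecc"] * rng.uniform(0.7, 1.0))
        phi = rng.uniform(0, math.pi) if sig["irregular"] else 0.0
        # keep the lesion fully inside the skull ellipse
        r = math.hypot(a, b)
        scale = 1.0
        dd = ((lcx - cx) / (skull_a - r)) ** 2 + ((lcy - cy) / (skull_b - r)) ** 2
        if dd > 0.85:
            scale = math.sqrt(0.85 / dd)
            lcx = cx + (lcx - cx) * scale
            lcy = cy + (lcy - cy) * scale
        cphi, sphi = math.cos(phi), math.sin(phi)
        xr = (xx - lcx) * cphi + (yy - lcy) * sphi
        yr = -(xx - lcx) * sphi + (yy - lcy) * cphi
        lesion = (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        if sig["irregular"]:
            ang = np.arctan2(yr, xr)
            wobble = 1.0 + 0.18 * np.sin(5 * ang + rng.uniform(0, 6.28))
            lesion = (xr / a) ** 2 + (yr / b) ** 2 <= wobble
        contrast = (110.0 if sig["bright"] else -85.0) * (1.0 - 0.7 * difficulty)
        img = np.where(lesion & brain, img + contrast, img)
        ys, xs = np.nonzero(lesion & brain)
        x1, x2 = xs.min(), xs.max() + 1
        y1, y2 = ys.min(), ys.max() + 1
        boxes = np.array([[x1, y1, x2, y2]], dtype=np.float64)
        meta.update(
            lesion_center=(float(lcx), float(lcy)),
            lesion_axes=(float(a), float(b)),
            bright=sig["bright"],
        )
    noise_sd = 3.0 + 9.0 * difficulty
    meta["noise_sd"] = noise_sd
    img = img + rng.normal(0, noise_sd, img.shape)
    image = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return PhantomRecord(image=image, category=category, boxes=boxes, meta=meta)


@dataclass
class DatasetManifest:
    train: list
    val: list
    category_counts: dict
    split_ratio: tuple = (8, 2)
    master_seed: int = 0

    @property
    def records(self):
        return self.train + self.val


def check_balance(counts) -> bool:
    """Tumor-category counts may differ by at most a factor of two."""
    tumor = [counts[c] for c in range(NOTUMOR)]
    return max(tumor) <= 2 * min(tumor) if min(tumor) > 0 else False


def generate_dataset(
    n: int,
    category_mix=(0.3, 0.25, 0.25, 0.2),
    master_seed: int = 0,
    difficulty: float = 0.0,
    size: int = IMAGE_SIZE,
) -> DatasetManifest:
    """Seeded dataset with a stratified 8:2 train/val split."""
    if n < 10:
        raise ValueError("need n >= 10")
    mix = np.asarray(category_mix, dtype=np.float64)
    mix = mix / mix.sum()
    counts = np.floor(mix * n).astype(int)
    for i in np.argsort(-(mix * n - counts))[: n - counts.sum()]:
        counts[i] += 1
    count_map = {c: int(counts[c]) for c in range(len(CATEGORIES))}
    if not check_balance(count_map):
        raise ValueError(
            f"category mix {count_map} violates the 2x balance rule among tumor categories"
        )
    root = np.random.default_rng(master_seed)
    seeds = root.integers(0, 2**31 - 1, size=n)
    records = []
    idx = 0
    for cat in range(len(CATEGORIES)):
        for _ in range(count_map[cat]):
            records.append(generate_phantom(int(seeds[idx]), cat, difficulty, size))
            idx += 1
    train, val = [], []
    for cat in range(len(CATEGORIES)):  # stratified 8:2 by category
        cat_recs = [r for r in records if r.category == cat]
        perm = np.random.default_rng(master_seed + 1000 + cat).permutation(len(cat_recs))
        n_val = round(len(cat_recs) * 0.2)
        val_ids = set(perm[:n_val].tolist())
        for i, r in enumerate(cat_recs):
            (val if i in val_ids else train).append(r)
    return DatasetManifest(
        train=train, val=val, category_counts=count_map, master_seed=master_seed
    )


# --------------------------------------------------------------- label I/O
def boxes_to_yolo_lines(labels: np.ndarray, size: tuple) -> list[str]:
    w, h = size
    lines = []
    for cat, x1, y1, x2, y2 in np.asarray(labels).reshape(-1, 5):
        lines.append(
            f"{int(cat)} {(x1 + x2) / 2 / w:.6f} {(y1 + y2) / 2 / h:.6f} "
            f"{(x2 - x1) / w:.6f} {(y2 - y1) / h:.6f}"
        )
    return lines


def yolo_lines_to_boxes(lines, size: tuple) -> np.ndarray:
    w, h = size
    rows = []
    for lineno, line in enumerate(lines, 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) < 5:
            raise ValueError(f"malformed YOLO label on line {lineno}: {line!r}")
        cat = int(parts[0])
        cx, cy, bw, bh = (float(p) for p in parts[1:5])
        rows.append(
            [cat, (cx - bw / 2) * w, (cy - bh / 2) * h, (cx + bw / 2) * w, (cy + bh / 2) * h]
        )
    return np.asarray(rows, dtype=np.float64).reshape(-1, 5)


def write_labels(manifest: DatasetManifest, out_dir, fmt: str = "yolo_txt", size: int = IMAGE_SIZE):
    """Write annotations for every record; returns the written paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    if fmt == "yolo_txt":
        for split, recs in (("train", manifest.train), ("val", manifest.val)):
            d = out_dir / split
            d.mkdir(exist_ok=True)
            for i, r in enumerate(recs):
                p = d / f"{split}_{i:05d}.txt"
                p.write_text("\n".join(boxes_to_yolo_lines(r.labels, (size, size))) + ("\n" if len(r.boxes) else ""))
                paths.append(p)
    elif fmt == "labelme_json":
        for split, recs in (("train", manifest.train), ("val", manifest.val)):
            d = out_dir / split
            d.mkdir(exist_ok=True)
            for i, r in enumerate(recs):
                shapes = [
                    {
                        "label": CATEGORIES[r.category],
                        "shape_type": "rectangle",
                        "points": [[float(b[0]), float(b[1])], [float(b[2]), float(b[3])]],
                    }
                    for b in r.boxes
                ]
                doc = {
                    "version": "5.0.0",
                    "imageHeight": size,
                    "imageWidth": size,
                    "imagePath": f"{split}_{i:05d}.png",
                    "shapes": shapes,
                }
                p = d / f"{split}_{i:05d}.json"
                p.write_text(json.dumps(doc, indent=1))
                paths.append(p)
    elif fmt == "coco_json":
        for split, recs in (("train", manifest.train), ("val", manifest.val)):
            images, annotations = [], []
            ann_id = 1
            for i, r in enumerate(recs):
                images.append(
                    {"id": i, "file_name": f"{split}_{i:05d}.png", "width": size, "height": size}
                )
                for b in r.boxes:
                    annotations.append(
                        {
                            "id": ann_id,
                            "image_id": i,
                            "category_id": r.category,
                            "bbox": [float(b[0]), float(b[1]), float(b[2] - b[0]), float(b[3] - b[1])],
                            "area": float((b[2] - b[0]) * (b[3] - b[1])),
                            "iscrowd": 0,
                        }
                    )
                    ann_id += 1
            doc = {
                "images": images,
                "annotations": annotations,
                "categories": [{"id": c, "name": n} for c, n in enumerate(CATEGORIES)],
            }
            p = out_dir / f"{split}.json"
            p.write_text(json.dumps(doc, indent=1))
            paths.append(p)
    else:
        raise ValueError(f"unknown label format {fmt!r}")
    return paths


def read_labels(path, fmt: str, size: int = IMAGE_SIZE) -> np.ndarray:
    """Read one annotation file back into a (N, 5) label array."""
    path = Path(path)
    try:
        if fmt == "yolo_txt":
            return yolo_lines_to_boxes(path.read_text().splitlines(), (size, size))
        if fmt == "labelme_json":
            doc = json.loads(path.read_text())
            rows = []
            for shape in doc["shapes"]:
                (x1, y1), (x2, y2) = shape["points"]
                rows.append([CATEGORIES.index(shape["label"]), x1, y1, x2, y2])
            return np.asarray(rows, dtype=np.float64).reshape(-1, 5)
        if fmt == "coco_json":
            doc = json.loads(path.read_text())
            rows = []
            for ann in doc["annotations"]:
                x, y, w, h = ann["bbox"]
                rows.append([ann["category_id"], x, y, x + w, y + h])
            return np.asarray(rows, dtype=np.float64).reshape(-1, 5)
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise ValueError(f"malformed {fmt} label file {path}: {exc}") from exc
    raise ValueError(f"unknown label format {fmt!r}")


def write_images(manifest: DatasetManifest, out_dir):
    from PIL import Image

    out_dir = Path(out_dir)
    paths = []
    for split, recs in (("train", manifest.train), ("val", manifest.val)):
        d = out_dir / split
        d.mkdir(parents=True, exist_ok=True)
        for i, r in enumerate(recs):
            p = d / f"{split}_{i:05d}.png"
            Image.fromarray(r.image).save(p)
            paths.append(p)
    return paths


def to_model_input(image: np.ndarray) -> np.ndarray:
    """Grayscale uint8 -> (3, H, W) float32 in [0, 1] (replicated channels)."""
    x = image.astype(np.float32) / 255.0
    if x.ndim == 2:
        x = np.stack([x, x, x])
    elif x.ndim == 3 and x.shape[2] in (1, 3):
        x = np.repeat(x, 3 // x.shape[2], axis=2).transpose(2, 0, 1)
    return x
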