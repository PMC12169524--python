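# repdet

A reparameterizable, anchor-free object detector for synthetic lesion
phantoms, implemented entirely on NumPy (including a small reverse-mode
autograd engine — no deep-learning framework required).

The package provides:

* **`repdet.reparam`** — batch-norm folding, 1×1→3×3 embedding, identity
  kernels, and the `RepConv` / `RepC3` blocks: multi-branch at training
  time, a single 3×3 convolution after fusion, with numerically
  equivalent outputs.
* **`repdet.fgconcat`** — `FGConcat`, an attention-gated drop-in
  replacement for channel concatenation (two conv branches re-weighted by
  a shared multi-scale attention instance, summed with the plain concat).
* **`repdet.model`** — the detector graph: stride-2 backbone, SPPF,
  PAN-style neck, decoupled distribution-regression head on 80/40/20
  grids (640 px input); feature flags `use_repconv` / `use_repc3` /
  `use_fgconcat` substitute the blocks above; whole-model fusion;
  exact parameter and FLOP counting.
* **`repdet.postprocess`** — box decoding, IoU, class-aware greedy NMS.
* **`repdet.evaluation`** — greedy matching, precision/recall, 101-point
  AP, AP50/mAP (IoU 0.50:0.05:0.95), confusion matrices, FPS, and
  gradient-weighted class-activation heatmaps.
* **`repdet.augment`** — mosaic, HSV jitter (0.015/0.7/0.4), random
  affine (translate 0.1, scale 0.5), horizontal flip (p=0.5), all with
  box remapping and seeded determinism.
* **`repdet.phantom`** — seeded generator of brain-like grayscale
  phantoms with 0 or 1 elliptical lesion across four categories
  (glioma/meningioma/pituitary/notumor), an 8:2 stratified split, the
  ≤2× class-balance rule, and YOLO-txt / labelme-JSON / COCO-JSON
  readers and writers.
* **`repdet.train`** — task-aligned assignment, BCE + CIoU + DFL loss,
  AdamW with linear lr decay (lr0 0.01 → ×0.01), desk-scale loop.

## CLI

```bash
repdet report                    # Params(M)/GFLOPs table, all scales x variants
repdet generate --out data --n 100 --seed 0
repdet train-cmd --out runs/t --scale n --flags all --steps 200 --imgsz 160 --n 64
repdet fuse runs/t/model.npz     # reparameterize to deploy form
repdet eval runs/t/model_fused.npz --out runs/eval --n 50
repdet predict runs/t/model_fused.npz image.png --out runs/pred
repdet heatmap runs/t/model.npz image.png --block join1 --out cam.png
```

## Notes

* FLOPs are counted as 2 × convolution multiply-accumulates plus 4
  flops/element each for batch norm and SiLU on convolution outputs
  (the convention of the reference tables); see `repdet/nn.py`.
* Everything is deterministic given seeds: model init, phantom
  generation, augmentation, and training batches.
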