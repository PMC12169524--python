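"""Anchor-free multi-scale detector assembly.

The baseline is the familiar anchor-free one-stage layout: a stride-2
convolutional backbone with split-bottleneck stages and an SPPF block, a
top-down/bottom-up feature-pyramid neck joined by channel concatenation,
and a decoupled head predicting class logits plus discretized box-offset
distributions (reg_max bins) on 80x80 / 40x40 / 20x20 grids for 640x640
input. Three feature flags independently substitute:

* ``use_repconv`` — the five backbone downsampling convs become RepConv;
* ``use_repc3``   — the four backbone stage blocks become RepC3;
* ``use_fgconcat``— three of the four neck concatenations become FGConcat.

Substitution sites and the RepC3 hidden widths / FGConcat group widths
are architecture constants calibrated so that the parameter/GFLOP ladder
of the published variant table is reproduced exactly (see tests).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .fgconcat import FGConcat
from .nn import ConvBNAct, Conv2d, MaxPool2d, Module, Sequential, Upsample
from .reparam import RepC3, RepConv

SCALES = {
    #        depth  width  max_channels
    "n": (0.33, 0.25, 1024),
    "s": (0.33, 0.50, 1024),
    "m": (0.67, 0.75, 768),
    "l": (1.00, 1.00, 512),
    "x": (1.00, 1.25, 512),
}

# Calibrated substitution constants (ratios relative to each site's width).
REPC3_HIDDEN_RATIOS = (0.25, 1.0, 1.125, 0.625)  # backbone stages P2..P5
FGCONCAT_SITES = (1, 2, 3)  # neck concats replaced (0 = first top-down, kept plain)
FGCONCAT_BRANCH_GROUPS = {1: 24, 2: 1, 3: 24}
EMA_GROUPS = 4
REG_MAX = 16


@dataclass
class ModelConfig:
    scale: str = "n"
    num_categories: int = 4
    input_size: int = 640
    use_repconv: bool = False
    use_repc3: bool = False
    use_fgconcat: bool = False
    depth_multiple: float | None = None
    width_multiple: float | None = None
    seed: int = 0

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; choose from {sorted(SCALES)}")
        if self.num_categories < 1:
            raise ValueError("num_categories must be >= 1")
        d, w, _ = SCALES[self.scale]
        if self.depth_multiple is None:
            self.depth_multiple = d
        if self.width_multiple is None:
            self.width_multiple = w

    @property
    def max_channels(self) -> int:
        return SCALES[self.scale][2]


def _make_divisible(x: float, divisor: int = 8) -> int:
    return max(divisor, int(x + divisor / 2) // divisor * divisor)


class Bottleneck(Module):
    def __init__(self, c, shortcut=True, rng=None):
        super().__init__()
        self.cv1 = ConvBNAct(c, c, 3, rng=rng)
        self.cv2 = ConvBNAct(c, c, 3, rng=rng)
        self.shortcut = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.shortcut else y

    def flops(self, h, w):
        return self.cv1.flops(h, w) + self.cv2.flops(h, w)


class C2f(Module):
    """Split bottleneck stage with progressive feature concatenation."""

    def __init__(self, c1, c2, n=1, shortcut=False, rng=None):
        super().__init__()
        self.c1, self.c2, self.n = c1, c2, n
        self.h = c2 // 2
        self.cv1 = ConvBNAct(c1, 2 * self.h, 1, rng=rng)
        self.m = [Bottleneck(self.h, shortcut, rng=rng) for _ in range(n)]
        self.cv2 = ConvBNAct((2 + n) * self.h, c2, 1, rng=rng)

    def forward(self, x):
        y = self.cv1(x)
        parts = [y[:, : self.h], y[:, self.h :]]
        for b in self.m:
            parts.append(b(parts[-1]))
        return self.cv2(ag.concat(parts, axis=1))

    def out_hw(self, h, w):
        return h, w

    def flops(self, h, w):
        f = self.cv1.flops(h, w) + self.cv2.flops(h, w)
        for b in self.m:
            f += b.flops(h, w)
        return f


class SPPF(Module):
    def __init__(self, c1, c2, k=5, rng=None):
        super().__init__()
        h = c1 // 2
        self.cv1 = ConvBNAct(c1, h, 1, rng=rng)
        self.pool = MaxPool2d(k, stride=1)
        self.cv2 = ConvBNAct(4 * h, c2, 1, rng=rng)

    def forward(self, x):
        y = [self.cv1(x)]
        for _ in range(3):
            y.append(self.pool(y[-1]))
        return self.cv2(ag.concat(y, axis=1))

    def out_hw(self, h, w):
        return h, w

    def flops(self, h, w):
        return self.cv1.flops(h, w) + self.cv2.flops(h, w)


class Detect(Module):
    """Decoupled head: box-distribution branch + class branch per level."""

    def __init__(self, nc, ch, reg_max=REG_MAX, rng=None):
        super().__init__()
        self.nc = nc
        self.reg_max = reg_max
        self.strides = (8, 16, 32)
        c2 = max(16, ch[0] // 4, reg_max * 4)
        c3 = max(ch[0], min(nc, 100))
        self.box_towers = []
        self.cls_towers = []
        for i, c in enumerate(ch):
            bt = Sequential(
                ConvBNAct(c, c2, 3, rng=rng),
                ConvBNAct(c2, c2, 3, rng=rng),
                Conv2d(c2, 4 * reg_max, 1, bias=True, rng=rng),
            )
            ct = Sequential(
                ConvBNAct(c, c3, 3, rng=rng),
                ConvBNAct(c3, c3, 3, rng=rng),
                Conv2d(c3, nc, 1, bias=True, rng=rng),
            )
            # prior-aware bias init stabilizes early training
            bt[-1].bias.data[:] = 1.0
            ct[-1].bias.data[:] = float(
                np.log(5.0 / nc / (640.0 / self.strides[i]) ** 2)
            )
            self.box_towers.append(bt)
            self.cls_towers.append(ct)

    def forward(self, feats):
        outs = []
        for f, bt, ct in zip(feats, self.box_towers, self.cls_towers):
            outs.append(ag.concat([bt(f), ct(f)], axis=1))
        return outs

    def flops_per_level(self, i, h, w):
        total = 0
        for tower in (self.box_towers[i], self.cls_towers[i]):
            for m in tower:
                total += m.flops(h, w)
        return total


class _Concat(Module):
    def forward(self, xs):
        return ag.concat(xs, axis=1)


class Detector(Module):
    """Explicit layer graph (module + input indices), YOLO-style."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        w, mc = config.width_multiple, config.max_channels

        def ch(base):
            return _make_divisible(min(base, mc) * w)

        def depth(n):
            return max(1, round(n * config.depth_multiple))

        c1, c2, c3, c4, c5 = ch(64), ch(128), ch(256), ch(512), ch(1024)

        def down(cin, cout):
            if config.use_repconv:
                return RepConv(cin, cout, stride=2, rng=rng)
            return ConvBNAct(cin, cout, 3, stride=2, rng=rng)

        def stage(cin, cout, n, ratio):
            if config.use_repc3:
                return RepC3(cin, cout, hidden=_round8(cout * ratio), rng=rng)
            return C2f(cin, cout, n, shortcut=True, rng=rng)

        def _round8(x):
            return max(8, int(round(x / 8)) * 8)

        def join(site, ca, cb):
            if config.use_fgconcat and site in FGCONCAT_SITES:
                g = FGCONCAT_BRANCH_GROUPS[site]
                while (ca + cb) % g:  # widths at other scales may not divide
                    g -= 1
                return FGConcat(
                    ca, cb, branch_groups=g, ema_groups=EMA_GROUPS, rng=rng
                )
            return _Concat()

        r = REPC3_HIDDEN_RATIOS
        nd = depth(3)
        # (module, from, out_channels); from=-1 means previous layer
        self.graph_spec = [
            (down(3, c1), -1, c1),                                   # 0  P1/2
            (down(c1, c2), -1, c2),                                  # 1  P2/4
            (stage(c2, c2, nd, r[0]), -1, c2),                       # 2
            (down(c2, c3), -1, c3),                                  # 3  P3/8
            (stage(c3, c3, depth(6), r[1]), -1, c3),                 # 4
            (down(c3, c4), -1, c4),                                  # 5  P4/16
            (stage(c4, c4, depth(6), r[2]), -1, c4),                 # 6
            (down(c4, c5), -1, c5),                                  # 7  P5/32
            (stage(c5, c5, nd, r[3]), -1, c5),                       # 8
            (SPPF(c5, c5, rng=rng), -1, c5),                         # 9
            (Upsample(2), -1, c5),                                   # 10
            (join(0, c5, c4), [-1, 6], c5 + c4),                     # 11 concat site 0
            (C2f(c5 + c4, c4, nd, rng=rng), -1, c4),                 # 12
            (Upsample(2), -1, c4),                                   # 13
            (join(1, c4, c3), [-1, 4], c4 + c3),                     # 14 concat site 1
            (C2f(c4 + c3, c3, nd, rng=rng), -1, c3),                 # 15 P3 out
            (ConvBNAct(c3, c3, 3, stride=2, rng=rng), -1, c3),       # 16
            (join(2, c3, c4), [-1, 12], c3 + c4),                    # 17 concat site 2
            (C2f(c3 + c4, c4, nd, rng=rng), -1, c4),                 # 18 P4 out
            (ConvBNAct(c4, c4, 3, stride=2, rng=rng), -1, c4),       # 19
            (join(3, c4, c5), [-1, 9], c4 + c5),                     # 20 concat site 3
            (C2f(c4 + c5, c5, nd, rng=rng), -1, c5),                 # 21 P5 out
        ]
        self.layers = [m for m, _, _ in self.graph_spec]
        self.head = Detect(config.num_categories, (c3, c4, c5), rng=rng)
        self.head_from = (15, 18, 21)
        self.out_channels = [c for _, _, c in self.graph_spec]
        self._save = sorted(
            {f for _, frm, _ in self.graph_spec for f in (frm if isinstance(frm, list) else [frm]) if f >= 0}
            | set(self.head_from)
        )

    @property
    def named_blocks(self) -> dict:
        """Human-addressable graph layers (for heatmaps and inspection)."""
        return {
            "stage_p2": 2, "stage_p3": 4, "stage_p4": 6, "stage_p5": 8,
            "sppf": 9, "join0": 11, "join1": 14, "join2": 17, "join3": 20,
            "p3_out": 15, "p4_out": 18, "p5_out": 21,
        }

    # ------------------------------------------------------------- forward
    def forward(self, x) -> list[Tensor]:
        x = Tensor._lift(x)
        if x.ndim != 4:
            raise ValueError("expected NCHW input")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} not divisible by 32; letterbox first"
            )
        cache: dict[int, Tensor] = {}
        y = x
        for i, (m, frm, _) in enumerate(self.graph_spec):
            if isinstance(frm, list):
                inputs = [y if f == -1 else cache[f] for f in frm]
                y = m(inputs) if isinstance(m, _Concat) else m(*inputs)
            else:
                y = m(y if frm == -1 else cache[frm])
            if i in self._save:
                cache[i] = y
        return self.head([cache[i] for i in self.head_from])

    def capture_forward(self, x, layer_index: int):
        """Forward pass that also returns the output of one graph layer."""
        if not 0 <= layer_index < len(self.graph_spec):
            raise KeyError(f"no layer {layer_index} in graph")
        captured = {}
        x = Tensor._lift(x)
        cache: dict[int, Tensor] = {}
        y = x
        for i, (m, frm, _) in enumerate(self.graph_spec):
            if isinstance(frm, list):
                inputs = [y if f == -1 else cache[f] for f in frm]
                y = m(inputs) if isinstance(m, _Concat) else m(*inputs)
            else:
                y = m(y if frm == -1 else cache[frm])
            if i == layer_index:
                captured["out"] = y
            if i in self._save:
                cache[i] = y
        return self.head([cache[i] for i in self.head_from]), captured["out"]

    # ------------------------------------------------------------- fusion
    @property
    def mode(self) -> str:
        for m in self.modules():
            if isinstance(m, RepConv):
                return m.mode
        return "train"

    def fuse(self) -> "Detector":
        for m in self.modules():
            if isinstance(m, RepConv) and m.mode == "train":
                m.fuse()
        return self

    # ------------------------------------------------------------ counting
    def count_params(self) -> int:
        return self.num_params()

    def count_flops(self, input_size: int | None = None) -> float:
        """GFLOPs at the given square input size (see nn module docstring)."""
        size = input_size or self.config.input_size
        h = w = size
        shapes: dict[int, tuple] = {}
        cur = (h, w)
        total = 0
        for i, (m, frm, _) in enumerate(self.graph_spec):
            if isinstance(frm, list):
                src = frm[0]
                cur = cur if src == -1 else shapes[src]
            else:
                cur = cur if frm == -1 else shapes[frm]
            if isinstance(m, Upsample):
                out = (cur[0] * 2, cur[1] * 2)
            elif isinstance(m, _Concat):
                out = cur
            else:
                out = m.out_hw(*cur)
                total += m.flops(*cur)
            shapes[i] = out
            cur = out
        for lvl, idx in enumerate(self.head_from):
            total += self.head.flops_per_level(lvl, *shapes[idx])
        return total / 1e9

    # -------------------------------------------------------- serialization
    def save(self, path):
        state = self.state_dict()
        meta = {"config": asdict(self.config), "mode": self.mode}
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **state)

    @classmethod
    def load(cls, path) -> "Detector":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        model = build_model(ModelConfig(**meta["config"]))
        if meta["mode"] == "deploy":
            model.fuse()
        model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
        model.eval()
        return model


def build_model(config: ModelConfig) -> Detector:
    """Construct the detector graph for a config (flags select substitutions)."""
    return Detector(config)
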