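"""Fine-grained feature-map fusion: a drop-in replacement for channel
concatenation.

Two inputs M1 (C1 channels) and M2 (C2 channels) are each lifted to
C1+C2 channels by a 1x1 conv followed by a 3x3 conv; both lifted maps
are re-weighted by a single shared multi-scale attention instance and
added elementwise to the plain concatenation of M1 and M2. The output
therefore always carries C1+C2 channels and degrades gracefully to a
plain concat when the branch weights are zero.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import Conv2d, ConvBNAct, Module, Parameter


class EMAAttention(Module):
    """Efficient multi-scale attention: grouped cross-spatial gating.

    Channels are split into ``groups``; each group is gated by a product of
    (a) directional pooled 1x1-conv sigmoid gates and (b) a cross-attention
    between a 3x3 local branch and the gated branch. Output shape equals
    input shape and the final gate is a sigmoid, so multiplicative weights
    lie in (0, 1).
    """

    def __init__(self, channels: int, groups: int = 4, rng=None):
        super().__init__()
        if channels % groups:
            raise ValueError(
                f"channels ({channels}) must be divisible by groups ({groups})"
            )
        self.channels = channels
        self.groups = groups
        cg = channels // groups
        self.conv1x1 = Conv2d(cg, cg, 1, bias=True, rng=rng)
        self.conv3x3 = Conv2d(cg, cg, 3, bias=True, rng=rng)
        self.gn_gamma = Parameter(np.ones(cg, dtype=np.float32))
        self.gn_beta = Parameter(np.zeros(cg, dtype=np.float32))

    def _group_norm(self, x: Tensor) -> Tensor:
        # per-sample, per-channel normalization within the grouped view
        mu = x.mean(axis=(2, 3), keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=(2, 3), keepdims=True)
        xhat = centered / (var + 1e-5).sqrt()
        cg = self.channels // self.groups
        return xhat * self.gn_gamma.reshape(1, cg, 1, 1) + self.gn_beta.reshape(1, cg, 1, 1)

    def forward(self, x: Tensor) -> Tensor:
        b, c, h, w = x.shape
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        g = self.groups
        cg = c // g
        xg = x.reshape(b * g, cg, h, w)
        # directional context: pool along each spatial axis, shared 1x1 conv
        x_h = ag.adaptive_avg_pool2d(xg, (None, 1))          # (bg, cg, h, 1)
        x_w = ag.adaptive_avg_pool2d(xg, (1, None))          # (bg, cg, 1, w)
        x_w = x_w.transpose(0, 1, 3, 2)                      # (bg, cg, w, 1)
        hw = self.conv1x1(ag.concat([x_h, x_w], axis=2))     # (bg, cg, h+w, 1)
        gate_h = hw[:, :, :h, :].sigmoid()
        gate_w = hw[:, :, h:, :].transpose(0, 1, 3, 2).sigmoid()
        x1 = self._group_norm(xg * gate_h * gate_w)
        x2 = self.conv3x3(xg)
        # cross-spatial: each branch's global descriptor attends the other
        a1 = ag.adaptive_avg_pool2d(x1, (1, 1)).reshape(b * g, 1, cg).softmax(axis=-1)
        a2 = ag.adaptive_avg_pool2d(x2, (1, 1)).reshape(b * g, 1, cg).softmax(axis=-1)
        m1 = x2.reshape(b * g, cg, h * w)
        m2 = x1.reshape(b * g, cg, h * w)
        weights = ((a1 @ m1) + (a2 @ m2)).reshape(b * g, 1, h, w).sigmoid()
        return (xg * weights).reshape(b, c, h, w)

    def flops(self, h, w) -> int:
        cg = self.channels // self.groups
        f = self.groups * 2 * cg * cg * (h + w) + self.groups * cg * (h + w)  # pooled 1x1
        f += self.groups * 2 * 9 * cg * cg * h * w + self.groups * cg * h * w  # 3x3
        return f


class FGConcat(Module):
    """Attention-gated replacement for ``concat([M1, M2])``."""

    def __init__(self, c1: int, c2: int, branch_groups: int = 1, ema_groups: int = 4, rng=None):
        super().__init__()
        self.c1, self.c2 = c1, c2
        c = c1 + c2
        if c % branch_groups:
            raise ValueError("C1+C2 must be divisible by branch_groups")
        self.branch1_conv1x1 = ConvBNAct(c1, c, 1, rng=rng)
        self.branch1_conv3x3 = ConvBNAct(c, c, 3, groups=branch_groups, rng=rng)
        self.branch2_conv1x1 = ConvBNAct(c2, c, 1, rng=rng)
        self.branch2_conv3x3 = ConvBNAct(c, c, 3, groups=branch_groups, rng=rng)
        self.ema = EMAAttention(c, ema_groups, rng=rng)  # one shared instance

    @property
    def c_out(self) -> int:
        return self.c1 + self.c2

    def forward(self, m1: Tensor, m2: Tensor) -> Tensor:
        if m1.shape[2:] != m2.shape[2:]:
            raise ValueError(f"spatial mismatch: {m1.shape[2:]} vs {m2.shape[2:]}")
        if m1.shape[1] != self.c1 or m2.shape[1] != self.c2:
            raise ValueError(
                f"channel mismatch: got ({m1.shape[1]}, {m2.shape[1]}), "
                f"expected ({self.c1}, {self.c2})"
            )
        top = self.branch1_conv3x3(self.branch1_conv1x1(m1))
        mid = ag.concat([m1, m2], axis=1)
        bottom = self.branch2_conv3x3(self.branch2_conv1x1(m2))
        return self.ema(top) + mid + self.ema(bottom)

    def out_hw(self, h, w):
        return h, w

    def flops(self, h, w) -> int:
        f = (
            self.branch1_conv1x1.flops(h, w)
            + self.branch1_conv3x3.flops(h, w)
            + self.branch2_conv1x1.flops(h, w)
            + self.branch2_conv3x3.flops(h, w)
        )
        return f + 2 * self.ema.flops(h, w)  # applied once per branch
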