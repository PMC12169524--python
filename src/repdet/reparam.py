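"""Kernel-fusion algebra and reparameterizable convolution blocks.

A multi-branch block (3x3 conv + 1x1 conv + optional identity, each with
its own batch norm) is trained as-is and then collapsed into a single
3x3 convolution whose output is identical up to floating-point error:

    fuse(block) = fold_bn(3x3) + pad_to_3x3(fold_bn(1x1)) + fold_bn(identity)

with biases summed. ``RepC3`` stacks three such blocks between 1x1
channel-adjusting convolutions, fusing the two parallel paths by
concatenation before the output projection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .nn import BatchNorm2d, Conv2d, ConvBNAct, FusedConvAct, Module, Parameter


# --------------------------------------------------------------------- types
@dataclass
class ConvKernel:
    """Plain-array convolution weights: (C_out, C_in, kH, kW) + optional bias."""

    weights: np.ndarray
    bias: np.ndarray | None = None
    stride: int = 1
    padding: int = field(default=-1)

    def __post_init__(self):
        self.weights = np.asarray(self.weights)
        if self.weights.ndim != 4:
            raise ValueError("ConvKernel weights must be rank-4 (Co, Ci, kH, kW)")
        kh, kw = self.weights.shape[2:]
        if kh != kw or kh not in (1, 3):
            raise ValueError(f"square 1x1 or 3x3 kernels only, got {kh}x{kw}")
        if self.padding < 0:
            self.padding = kh // 2
        if self.bias is not None:
            self.bias = np.asarray(self.bias)
            if self.bias.shape != (self.weights.shape[0],):
                raise ValueError("bias length must equal C_out")

    @property
    def c_out(self) -> int:
        return self.weights.shape[0]

    @property
    def k(self) -> int:
        return self.weights.shape[2]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Run the convolution on a plain array (no autograd)."""
        with ag.no_grad():
            b = None if self.bias is None else Tensor(self.bias)
            return ag.conv2d(
                Tensor(x), Tensor(self.weights), b, self.stride, self.padding
            ).data


@dataclass
class BNParams:
    """Per-channel batch-norm statistics and affine parameters."""

    mean: np.ndarray
    var: np.ndarray
    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-3

    def __post_init__(self):
        self.mean, self.var, self.gamma, self.beta = (
            np.atleast_1d(np.asarray(v)) for v in (self.mean, self.var, self.gamma, self.beta)
        )
        lengths = {v.shape for v in (self.mean, self.var, self.gamma, self.beta)}
        if len(lengths) != 1:
            raise ValueError("BNParams vectors must share a common length")
        if np.any(self.var < 0):
            raise ValueError("variance must be non-negative")
        if not self.eps > 0 and not np.all(self.var > 0):
            raise ValueError("eps must be positive when any variance is zero")

    @property
    def channels(self) -> int:
        return self.mean.shape[0]

    def apply(self, x: np.ndarray) -> np.ndarray:
        """Normalize a NCHW array channel-wise: gamma*(x-mean)/sqrt(var+eps)+beta."""
        shape = (1, -1, 1, 1)
        scale = (self.gamma / np.sqrt(self.var + self.eps)).reshape(shape)
        shift = (self.beta - self.mean * self.gamma / np.sqrt(self.var + self.eps)).reshape(shape)
        return x * scale + shift

    @staticmethod
    def identity(channels: int, eps: float = 0.0) -> "BNParams":
        return BNParams(
            np.zeros(channels), np.ones(channels), np.ones(channels),
            np.zeros(channels), eps=max(eps, 1e-30),
        )


# ----------------------------------------------------------------- fusion ops
def fold_bn(kernel: ConvKernel, bn: BNParams) -> ConvKernel:
    """Absorb a following batch norm into the convolution's weights and bias."""
    if bn.channels != kernel.c_out:
        raise ValueError(
            f"channel mismatch: kernel C_out={kernel.c_out}, BN has {bn.channels}"
        )
    scale = bn.gamma / np.sqrt(bn.var + bn.eps)
    weights = kernel.weights * scale[:, None, None, None]
    bias = np.zeros(kernel.c_out, dtype=kernel.weights.dtype) if kernel.bias is None else kernel.bias
    bias = bn.beta + (bias - bn.mean) * scale
    return ConvKernel(weights, bias, kernel.stride, kernel.padding)


def pad_1x1_to_3x3(kernel: ConvKernel) -> ConvKernel:
    """Embed a 1x1 kernel at the center of a zero 3x3 kernel."""
    if kernel.k != 1:
        raise ValueError(f"expected a 1x1 kernel, got {kernel.k}x{kernel.k}")
    co, ci = kernel.weights.shape[:2]
    weights = np.zeros((co, ci, 3, 3), dtype=kernel.weights.dtype)
    weights[:, :, 1, 1] = kernel.weights[:, :, 0, 0]
    return ConvKernel(weights, kernel.bias, kernel.stride, padding=1)


def identity_to_3x3(channels: int, bn: BNParams | None = None) -> ConvKernel:
    """Express the identity map (optionally followed by BN) as a 3x3 conv."""
    if channels < 1:
        raise ValueError("channels must be >= 1")
    weights = np.zeros((channels, channels, 3, 3), dtype=np.float64)
    weights[np.arange(channels), np.arange(channels), 1, 1] = 1.0
    kernel = ConvKernel(weights, None, stride=1, padding=1)
    return kernel if bn is None else fold_bn(kernel, bn)


def silu(x):
    """Elementwise x * sigmoid(x); accepts scalars or arrays."""
    if isinstance(x, Tensor):
        return x.silu()
    arr = np.asarray(x, dtype=np.float64 if np.asarray(x).dtype != np.float32 else np.float32)
    out = arr * (1.0 / (1.0 + np.exp(-arr)))
    return out if arr.ndim else float(out)


def _bn_params(bn: BatchNorm2d) -> BNParams:
    # fold in float64: a single rounding at the end beats chained float32 ops
    return BNParams(
        bn.running_mean.astype(np.float64),
        bn.running_var.astype(np.float64),
        bn.gamma.data.astype(np.float64),
        bn.beta.data.astype(np.float64),
        bn.eps,
    )


# -------------------------------------------------------------------- RepConv
class RepConv(Module):
    """Train-time multi-branch block, deploy-time single 3x3 conv + SiLU.

    Branches: 3x3 conv + BN, 1x1 conv + BN, and (when C_in == C_out and
    stride == 1) an identity path holding only a BN.
    """

    def __init__(self, cin, cout, stride=1, identity=None, rng=None):
        super().__init__()
        self.cin, self.cout, self.stride = cin, cout, stride
        if identity is None:
            identity = cin == cout and stride == 1
        if identity and (cin != cout or stride != 1):
            raise ValueError("identity branch requires C_in == C_out and stride 1")
        self.conv3 = Conv2d(cin, cout, 3, stride, bias=False, rng=rng)
        self.bn3 = BatchNorm2d(cout)
        self.conv1 = Conv2d(cin, cout, 1, stride, bias=False, rng=rng)
        self.bn1 = BatchNorm2d(cout)
        self.bn_id = BatchNorm2d(cout) if identity else None
        self.fused: FusedConvAct | None = None

    @property
    def mode(self) -> str:
        return "deploy" if self.fused is not None else "train"

    def forward(self, x: Tensor) -> Tensor:
        if self.fused is not None:
            return self.fused(x)
        y = self.bn3(self.conv3(x)) + self.bn1(self.conv1(x))
        if self.bn_id is not None:
            y = y + self.bn_id(x)
        return y.silu()

    def fuse(self) -> "RepConv":
        """Collapse all branches into ``self.fused`` (idempotent, warns on repeat)."""
        if self.fused is not None:
            warnings.warn("RepConv already fused; fuse() is a no-op", stacklevel=2)
            return self
        k = fuse_branches(
            ConvKernel(self.conv3.weight.data.astype(np.float64), None, self.stride, 1),
            _bn_params(self.bn3),
            ConvKernel(self.conv1.weight.data.astype(np.float64), None, self.stride, 0),
            _bn_params(self.bn1),
            None if self.bn_id is None else _bn_params(self.bn_id),
        )
        conv = Conv2d(self.cin, self.cout, 3, self.stride, bias=True)
        conv.weight = Parameter(k.weights.astype(np.float32))
        conv.bias = Parameter(k.bias.astype(np.float32))
        self.fused = FusedConvAct(conv, act=True)
        # drop train-time branches so they no longer show up in parameters()
        self.conv3 = self.bn3 = self.conv1 = self.bn1 = self.bn_id = None
        return self

    def out_hw(self, h, w):
        return (h + 2 - 3) // self.stride + 1, (w + 2 - 3) // self.stride + 1

    def flops(self, h, w) -> int:
        if self.fused is not None:
            return self.fused.flops(h, w)
        ho, wo = self.out_hw(h, w)
        per_elem = 8 * self.cout * ho * wo  # BN + activation, per branch conv
        macs3 = 9 * self.cin * self.cout * ho * wo
        macs1 = self.cin * self.cout * ho * wo
        return 2 * macs3 + per_elem + 2 * macs1 + per_elem


def fuse_branches(
    k3: ConvKernel,
    bn3: BNParams,
    k1: ConvKernel,
    bn1: BNParams,
    bn_id: BNParams | None,
) -> ConvKernel:
    """Pure algebra: merge the three branch kernels into one 3x3 kernel."""
    fused = fold_bn(k3, bn3)
    one = pad_1x1_to_3x3(fold_bn(k1, bn1))
    weights = fused.weights + one.weights
    bias = fused.bias + one.bias
    if bn_id is not None:
        ident = identity_to_3x3(fused.c_out, bn_id)
        weights = weights + ident.weights.astype(weights.dtype)
        bias = bias + ident.bias
    return ConvKernel(weights, bias, k3.stride, padding=1)


def fuse_repconv(block: RepConv) -> RepConv:
    """Functional alias for :meth:`RepConv.fuse`."""
    return block.fuse()


# ---------------------------------------------------------------------- RepC3
class RepC3(Module):
    """Dual-path bottleneck: two 1x1 input projections, one path through a
    stack of N=3 RepConvs, fused by concat + 1x1 output projection."""

    N_REPEATS = 3  # fixed stack depth

    def __init__(self, cin, cout, hidden=None, rng=None):
        super().__init__()
        self.cin, self.cout = cin, cout
        self.hidden = cout // 2 if hidden is None else hidden
        self.cv1 = ConvBNAct(cin, self.hidden, 1, rng=rng)
        self.cv2 = ConvBNAct(cin, self.hidden, 1, rng=rng)
        self.reps = [
            RepConv(self.hidden, self.hidden, rng=rng) for _ in range(self.N_REPEATS)
        ]
        self.cv3 = ConvBNAct(2 * self.hidden, cout, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {x.shape[1]}")
        f1 = self.cv1(x)
        f3 = self.cv2(x)
        for rep in self.reps:
            f3 = rep(f3)
        return self.cv3(ag.concat([f1, f3], axis=1))

    def fuse(self):
        for rep in self.reps:
            rep.fuse()
        return self

    def out_hw(self, h, w):
        return h, w

    def flops(self, h, w) -> int:
        f = self.cv1.flops(h, w) + self.cv2.flops(h, w) + self.cv3.flops(h, w)
        for rep in self.reps:
            f += rep.flops(h, w)
        return f
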