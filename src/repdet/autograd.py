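"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements only the operator set the detector needs: broadcast arithmetic,
reductions, indexing, concatenation, 2-D convolution (via im2col), max
pooling, nearest upsampling and a handful of pointwise nonlinearities.
Gradient checks for every op live in the test suite.
"""

from __future__ import annotations

import contextlib
from typing import Iterable, Sequence

import numpy as np

_GRAD_ENABLED = True

#: number of conv2d invocations since process start (operation-count probes)
CONV_CALLS = 0


@contextlib.contextmanager
def no_grad():
    """Disable graph construction inside the context (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        if isinstance(data, np.ndarray):
            self.data = data
        elif isinstance(data, np.generic):  # 0-d results keep their precision
            self.data = np.asarray(data)
        else:
            self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad and _GRAD_ENABLED
        self._backward = None
        self._prev: tuple = ()

    # ------------------------------------------------------------------ infra
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __len__(self):
        return len(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self):
        self.grad = None

    def _accum(self, g: np.ndarray):
        g = g.astype(self.data.dtype, copy=False)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self, grad: np.ndarray | None = None):
        """Reverse-mode sweep from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative topological sort: graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # --------------------------------------------------------------- helpers
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"], backward):
        out = Tensor(data)
        parents = [p for p in parents if isinstance(p, Tensor)]
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # ------------------------------------------------------------ arithmetic
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            if self.requires_grad:
                self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / (other.data * other.data), other.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._lift(other) / self

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g @ np.swapaxes(other.data, -1, -2), self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(np.swapaxes(self.data, -1, -2) @ g, other.shape))

        return self._make(out_data, (self, other), backward)

    # ------------------------------------------------------------- pointwise
    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def abs(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), backward)

    def sigmoid(self):
        s = _sigmoid(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * s * (1.0 - s))

        return self._make(s, (self,), backward)

    def silu(self):
        s = _sigmoid(self.data)
        out_data = self.data * s

        def backward(g):
            if self.requires_grad:
                self._accum(g * (s + self.data * s * (1.0 - s)))

        return self._make(out_data, (self,), backward)

    def atan(self):
        def backward(g):
            if self.requires_grad:
                self._accum(g / (1.0 + self.data * self.data))

        return self._make(np.arctan(self.data), (self,), backward)

    def clip(self, lo: float | None, hi: float | None):
        out_data = np.clip(self.data, lo, hi)
        mask = np.ones_like(self.data)
        if lo is not None:
            mask = mask * (self.data >= lo)
        if hi is not None:
            mask = mask * (self.data <= hi)

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(out_data, (self,), backward)

    def maximum(self, other):
        other = self._lift(other)
        out_data = np.maximum(self.data, other.data)
        take_self = self.data >= other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.shape))

        return self._make(out_data, (self, other), backward)

    def minimum(self, other):
        other = self._lift(other)
        out_data = np.minimum(self.data, other.data)
        take_self = self.data <= other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * take_self, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * ~take_self, other.shape))

        return self._make(out_data, (self, other), backward)

    # ------------------------------------------------------------ reductions
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis=None, keepdims: bool = False):
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        expanded = self.data.max(axis=axis, keepdims=True)
        mask = self.data == expanded
        count = mask.sum(axis=axis, keepdims=True)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                g = np.expand_dims(g, axes)
            self._accum(np.broadcast_to(g, self.shape) * mask / count)

        return self._make(out_data, (self,), backward)

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        s = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * s).sum(axis=axis, keepdims=True)
                self._accum(s * (g - dot))

        return self._make(s, (self,), backward)

    def log_softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(shifted).sum(axis=axis, keepdims=True))
        out_data = shifted - lse
        s = np.exp(out_data)

        def backward(g):
            if self.requires_grad:
                self._accum(g - s * g.sum(axis=axis, keepdims=True))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------- structure
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(self.data.transpose(axes), (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        return self._make(out_data, (self,), backward)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    out = Tensor(out_data)
    if _GRAD_ENABLED and any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


# ---------------------------------------------------------------- conv2d ops
def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    # (N, C, kh, kw, Ho, Wo) without copying via stride tricks
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows.transpose(0, 4, 5, 1, 2, 3)).reshape(
        n * ho * wo, c * kh * kw
    )
    return cols, ho, wo


def _col2im(dcols: np.ndarray, x_shape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    dxp = np.zeros((n, c, hp, wp), dtype=dcols.dtype)
    d6 = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += d6[
                :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def conv2d(
    x: Tensor,
    weight: Tensor,
    bias: Tensor | None = None,
    stride: int = 1,
    padding: int = 0,
    groups: int = 1,
) -> Tensor:
    """2-D cross-correlation, NCHW layout, square kernels."""
    global CONV_CALLS
    CONV_CALLS += 1
    x = Tensor._lift(x)
    weight = Tensor._lift(weight)
    n, cin, h, w = x.shape
    cout, cin_g, kh, kw = weight.shape
    if cin_g * groups != cin:
        raise ValueError(
            f"conv2d channel mismatch: input {cin}, weight expects {cin_g * groups}"
        )
    cols, ho, wo = _im2col(x.data, kh, kw, stride, padding)
    if groups == 1:
        out = cols @ weight.data.reshape(cout, -1).T
    else:
        cols_g = cols.reshape(-1, groups, cin_g * kh * kw)
        w_g = weight.data.reshape(groups, cout // groups, -1)
        out = np.einsum("ngk,gok->ngo", cols_g, w_g).reshape(-1, cout)
    out = out.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out = out + bias.data.reshape(1, -1, 1, 1)
    out = np.ascontiguousarray(out)

    def backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        if weight.requires_grad:
            if groups == 1:
                dw = gmat.T @ cols
            else:
                gm = gmat.reshape(-1, groups, cout // groups)
                cg = cols.reshape(-1, groups, cin_g * kh * kw)
                dw = np.einsum("ngo,ngk->gok", gm, cg).reshape(cout, -1)
            weight._accum(dw.reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gmat.sum(axis=0))
        if x.requires_grad:
            if groups == 1:
                dcols = gmat @ weight.data.reshape(cout, -1)
            else:
                gm = gmat.reshape(-1, groups, cout // groups)
                w_g2 = weight.data.reshape(groups, cout // groups, -1)
                dcols = np.einsum("ngo,gok->ngk", gm, w_g2).reshape(
                    -1, cin * kh * kw // groups * groups
                )
            x._accum(_col2im(dcols, x.shape, kh, kw, stride, padding))

    parents = (x, weight) if bias is None else (x, weight, bias)
    out_t = Tensor(out)
    if _GRAD_ENABLED and any(p.requires_grad for p in parents):
        out_t.requires_grad = True
        out_t._prev = parents
        out_t._backward = backward
    return out_t


def max_pool2d(x: Tensor, kernel: int, stride: int = 1, padding: int = 0) -> Tensor:
    x = Tensor._lift(x)
    n, c, h, w = x.shape
    xd = x.data
    if padding:
        xd = np.pad(
            xd, ((0, 0), (0, 0), (padding,) * 2, (padding,) * 2), constant_values=-np.inf
        )
    ho = (xd.shape[2] - kernel) // stride + 1
    wo = (xd.shape[3] - kernel) // stride + 1
    s0, s1, s2, s3 = xd.strides
    windows = np.lib.stride_tricks.as_strided(
        xd,
        shape=(n, c, ho, wo, kernel, kernel),
        strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        writeable=False,
    )
    flat = windows.reshape(n, c, ho, wo, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        dxp = np.zeros((n, c, xd.shape[2], xd.shape[3]), dtype=g.dtype)
        ki, kj = np.unravel_index(arg, (kernel, kernel))
        ii = np.arange(ho)[None, None, :, None] * stride + ki
        jj = np.arange(wo)[None, None, None, :] * stride + kj
        nn = np.arange(n)[:, None, None, None]
        cc = np.arange(c)[None, :, None, None]
        np.add.at(dxp, (nn, cc, ii, jj), g)
        if padding:
            dxp = dxp[:, :, padding : padding + h, padding : padding + w]
        x._accum(dxp)

    out_t = Tensor(np.ascontiguousarray(out))
    if _GRAD_ENABLED and x.requires_grad:
        out_t.requires_grad = True
        out_t._prev = (x,)
        out_t._backward = backward
    return out_t


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    x = Tensor._lift(x)
    out = x.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        if x.requires_grad:
            n, c, h, w = x.shape
            x._accum(g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))

    out_t = Tensor(out)
    if _GRAD_ENABLED and x.requires_grad:
        out_t.requires_grad = True
        out_t._prev = (x,)
        out_t._backward = backward
    return out_t


def adaptive_avg_pool2d(x: Tensor, output: int | tuple) -> Tensor:
    """Supports the three cases the attention block needs: (1,1), (H,1), (1,W)."""
    x = Tensor._lift(x)
    n, c, h, w = x.shape
    oh, ow = (output, output) if isinstance(output, int) else output
    oh = h if oh is None else oh
    ow = w if ow is None else ow
    if (oh, ow) == (1, 1):
        return x.mean(axis=(2, 3), keepdims=True)
    if oh == h and ow == 1:
        return x.mean(axis=3, keepdims=True)
    if oh == 1 and ow == w:
        return x.mean(axis=2, keepdims=True)
    raise NotImplementedError(f"adaptive_avg_pool2d to {(oh, ow)}")
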