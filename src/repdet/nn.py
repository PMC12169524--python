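"""Layer abstractions over the autograd engine.

Conventions follow the usual detection-framework style: NCHW float32,
convolutions are bias-free when followed by batch norm, SiLU activations,
and every layer knows how to report its own parameter and FLOP cost.

FLOP accounting (used for the printed GFLOPs figures): a convolution
contributes 2 multiply-accumulates per output element and weight tap,
+4 flops/element when batch norm follows, +4 flops/element for its
activation, +1 flop/element for a standalone bias. Structural ops
(concat, pooling windows, upsampling) are not counted.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float32), requires_grad=True)


class Module:
    """Base class: parameter discovery, train/eval mode, state dicts."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- flat (name -> array) serialization -------------------------------
    def state_dict(self, prefix: str = "") -> dict:
        state = {}
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                state[full] = value.data
            elif isinstance(value, np.ndarray):  # buffers (running stats)
                state[full] = value
            elif isinstance(value, Module):
                state.update(value.state_dict(full))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.state_dict(f"{full}.{i}"))
        return state

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, value in vars(self).items():
            full = f"{prefix}.{name}" if prefix else name
            if isinstance(value, Parameter):
                value.data = np.asarray(state[full], dtype=np.float32).reshape(
                    value.data.shape
                )
            elif isinstance(value, np.ndarray):
                setattr(self, name, np.asarray(state[full], dtype=value.dtype))
            elif isinstance(value, Module):
                value.load_state_dict(state, full)
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state_dict(state, f"{full}.{i}")


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = float(np.sqrt(6.0 / fan_in)) if fan_in > 0 else 0.0
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


def calibrate_bn(model: "Module", batch) -> "Module":
    """Set every batch norm's running statistics from one forward pass.

    Freshly built models carry the (0, 1) placeholder statistics; folding or
    evaluating such a net lets activation magnitudes drift with depth. One
    calibration pass pins the running stats to actual batch statistics.
    """
    mods = [m for m in model.modules() if isinstance(m, BatchNorm2d)]
    saved = [(m.momentum, m.training) for m in mods]
    for m in mods:
        m.momentum, m.training = 1.0, True
    with ag.no_grad():
        model(batch)
    for m, (mom, tr) in zip(mods, saved):
        m.momentum, m.training = mom, tr
    return model


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, padding=None, groups=1, bias=True, rng=None):
        super().__init__()
        self.cin, self.cout, self.k = cin, cout, k
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = cin // groups * k * k
        self.weight = Parameter(kaiming_uniform(rng, (cout, cin // groups, k, k), fan_in))
        self.bias = (
            Parameter(
                rng.uniform(-1, 1, size=cout).astype(np.float32) / np.sqrt(fan_in)
            )
            if bias
            else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding, self.groups)

    def out_hw(self, h, w):
        ho = (h + 2 * self.padding - self.k) // self.stride + 1
        wo = (w + 2 * self.padding - self.k) // self.stride + 1
        return ho, wo

    def flops(self, h, w) -> int:
        ho, wo = self.out_hw(h, w)
        macs = self.cout * (self.cin // self.groups) * self.k * self.k * ho * wo
        f = 2 * macs
        if self.bias is not None:
            f += self.cout * ho * wo
        return f


class BatchNorm2d(Module):
    def __init__(self, c, eps: float = 1e-3, momentum: float = 0.03):
        super().__init__()
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.reshape(-1) * n / max(n - 1, 1)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean
                + self.momentum * mu.data.reshape(-1)
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * unbiased
            ).astype(np.float32)
            xhat = centered / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, -1, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = (x - Tensor(mu)) * Tensor(1.0 / sd)
        g = self.gamma.reshape(1, self.c, 1, 1)
        b = self.beta.reshape(1, self.c, 1, 1)
        return xhat * g + b

    def flops(self, h, w) -> int:
        return 4 * self.c * h * w


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class ConvBNAct(Module):
    """Conv -> BN -> SiLU, the standard detector building block."""

    def __init__(self, cin, cout, k=1, stride=1, groups=1, act=True, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride, groups=groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn(self.conv(x))
        return y.silu() if self.act else y

    def out_hw(self, h, w):
        return self.conv.out_hw(h, w)

    def flops(self, h, w) -> int:
        ho, wo = self.conv.out_hw(h, w)
        f = self.conv.flops(h, w) + self.bn.flops(ho, wo)
        if self.act:
            f += 4 * self.conv.cout * ho * wo
        return f


class FusedConvAct(Module):
    """Single conv with bias (+ optional SiLU): the deploy-time form."""

    def __init__(self, conv: Conv2d, act: bool = True):
        super().__init__()
        self.conv = conv
        self.act = act

    def forward(self, x: Tensor) -> Tensor:
        y = self.conv(x)
        return y.silu() if self.act else y

    def out_hw(self, h, w):
        return self.conv.out_hw(h, w)

    def flops(self, h, w) -> int:
        ho, wo = self.conv.out_hw(h, w)
        f = self.conv.flops(h, w)
        if self.act:
            f += 4 * self.conv.cout * ho * wo
        return f


class MaxPool2d(Module):
    def __init__(self, k, stride=1, padding=None):
        super().__init__()
        self.k, self.stride = k, stride
        self.padding = k // 2 if padding is None else padding

    def forward(self, x: Tensor) -> Tensor:
        return ag.max_pool2d(x, self.k, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return ag.upsample_nearest2d(x, self.scale)


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x):
        for m in self.mods:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self.mods)

    def __getitem__(self, i):
        return self.mods[i]
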