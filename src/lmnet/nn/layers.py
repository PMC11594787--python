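"""Module system and standard layers built on the autograd core.

Every layer knows how to report its own multiply-accumulate cost through
``own_macs`` so the complexity module can produce per-layer accounts by
tracing one forward pass.  The counting convention is documented in
:mod:`lmnet.complexity`.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = [
    "Module", "Sequential", "Identity", "Conv2d", "BatchNorm2d", "Linear",
    "ReLU", "Sigmoid", "MaxPool2d", "GlobalAvgPool", "trace_shapes",
]

# global trace sink used by the complexity module
_TRACE: list | None = None


@contextmanager
def trace_shapes(records: list):
    """Record ``(module, input_shape, output_shape)`` for every module call."""
    global _TRACE
    prev, _TRACE = _TRACE, records
    try:
        yield records
    finally:
        _TRACE = prev


class Module:
    """Base class: children and parameters discovered from attributes."""

    def __init__(self):
        self.training = True

    # -- tree ----------------------------------------------------------
    def children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_modules(self, prefix: str = ""):
        yield prefix or "", self
        for name, child in self.children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield (f"{prefix}.{name}" if prefix else name), value
        for name, child in self.children():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def train(self):
        for _, m in self.named_modules():
            m.training = True
        return self

    def eval(self):
        for _, m in self.named_modules():
            m.training = False
        return self

    # -- state ---------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                key = f"{name}." if name else ""
                state[f"{key}running_mean"] = m.running_mean.copy()
                state[f"{key}running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = np.asarray(state[name], dtype=np.float32).reshape(p.data.shape)
        for name, m in self.named_modules():
            if isinstance(m, BatchNorm2d):
                key = f"{name}." if name else ""
                m.running_mean = np.asarray(state[f"{key}running_mean"], dtype=np.float32)
                m.running_var = np.asarray(state[f"{key}running_var"], dtype=np.float32)

    # -- execution -----------------------------------------------------
    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        out = self.forward(x)
        if _TRACE is not None:
            _TRACE.append((self, tuple(x.shape), tuple(out.shape)))
        return out

    def own_macs(self, in_shape, out_shape) -> int:
        """Multiply-accumulate cost of this module's *inline* work only."""
        return 0


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.layers = list(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x):
        return x


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, dilation: int = 1,
                 groups: int = 1, bias: bool = False,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ValueError(
                f"channels ({in_channels}->{out_channels}) not divisible by groups={groups}")
        self.in_channels, self.out_channels = in_channels, out_channels
        self.kernel_size, self.stride = kernel_size, stride
        self.padding, self.dilation, self.groups = padding, dilation, groups
        rng = rng or np.random.default_rng()
        fan_in = in_channels // groups * kernel_size ** 2
        scale = math.sqrt(2.0 / fan_in)  # He initialisation for ReLU nets
        self.weight = Parameter(rng.normal(
            0.0, scale, (out_channels, in_channels // groups, kernel_size, kernel_size)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return ag.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                         self.dilation, self.groups)

    def own_macs(self, in_shape, out_shape):
        _, cout, ho, wo = out_shape
        macs = (self.kernel_size ** 2 * (self.in_channels // self.groups)
                * cout * ho * wo)
        if self.bias is not None:
            macs += cout * ho * wo
        return macs


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps, self.momentum = eps, momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return ag.batch_norm(x, self.weight, self.bias, self.running_mean,
                             self.running_var, self.training, self.momentum, self.eps)

    def own_macs(self, in_shape, out_shape):
        return int(np.prod(out_shape[1:]))


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        rng = rng or np.random.default_rng()
        bound = math.sqrt(1.0 / in_features)
        self.weight = Parameter(rng.uniform(-bound, bound, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = ag.matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out

    def own_macs(self, in_shape, out_shape):
        macs = self.in_features * self.out_features
        if self.bias is not None:
            macs += self.out_features
        n = in_shape[0]
        return macs * n


class ReLU(Module):
    def forward(self, x):
        return ag.relu(x)

    def own_macs(self, in_shape, out_shape):
        return int(np.prod(out_shape[1:]))


class Sigmoid(Module):
    def forward(self, x):
        return ag.sigmoid(x)

    def own_macs(self, in_shape, out_shape):
        return int(np.prod(out_shape[1:]))


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0):
        super().__init__()
        self.kernel_size, self.stride, self.padding = kernel_size, stride, padding

    def forward(self, x):
        return ag.max_pool2d(x, self.kernel_size, self.stride, self.padding)

    def own_macs(self, in_shape, out_shape):
        return int(np.prod(out_shape[1:]))


class GlobalAvgPool(Module):
    """(N, C, H, W) -> (N, C)."""

    def forward(self, x):
        return ag.mean(x, axis=(2, 3))

    def own_macs(self, in_shape, out_shape):
        return int(np.prod(out_shape[1:]))
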