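"""Channel/spatial attention operators: coordinate attention, CBAM, SE, ECA.

All four follow the same contract: the operator computes multiplicative
gates in (0, 1) from pooled channel descriptors and returns the input
rescaled by those gates, preserving shape exactly.

Coordinate attention factorises channel attention into a per-row and a
per-column pooled descriptor so the gates carry positional information —
useful when the discriminative structure (a lesion, an insect body) sits
at a consistent place in the receptive field.  SE gates channels through
a bottleneck MLP on the globally pooled descriptor; ECA replaces that MLP
with a 1-D convolution across channels; CBAM applies a channel gate then
a spatial gate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .nn import (BatchNorm2d, Conv2d, Identity, Module, ReLU, Sigmoid, F)
from .nn.autograd import Parameter, Tensor

__all__ = [
    "AttentionConfig", "CoordinateAttention", "CBAM", "SqueezeExcitation",
    "ECAAttention", "build_attention", "eca_kernel_size",
]


@dataclass
class AttentionConfig:
    """Which attention operator to build and with what hyperparameters.

    ``reduction_r`` controls the bottleneck width of CA/SE and of the CBAM
    channel gate; ``spatial_kernel`` is the CBAM spatial convolution size
    (odd); ``eca_gamma``/``eca_b`` parameterise the ECA kernel-size rule.
    """

    kind: str = "CA"            # one of CA, CBAM, SE, ECA, none
    reduction_r: int = 4
    spatial_kernel: int = 7
    eca_gamma: float = 2.0
    eca_b: float = 1.0

    def __post_init__(self):
        if self.kind not in {"CA", "CBAM", "SE", "ECA", "none"}:
            raise ValueError(f"unknown attention kind {self.kind!r}")
        if self.reduction_r < 1:
            raise ValueError("reduction_r must be a positive integer")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")


def _bottleneck_width(channels: int, reduction: int) -> int:
    width = channels // reduction
    if width < 1:
        raise ValueError(
            f"reduction {reduction} collapses {channels} channels below width 1")
    return width


class CoordinateAttention(Module):
    """Coordinate attention: directional pooling -> shared bottleneck -> two gates.

    The input is average-pooled along width (one descriptor per row) and
    along height (one per column); the two descriptors are concatenated
    along the spatial axis, passed through a shared pointwise transform to
    ``channels / reduction_r`` width (BN + ReLU), split back, expanded to
    full channel width by two pointwise transforms, and squashed by a
    logistic.  The input is multiplied by the broadcast outer product of
    the two gates.
    """

    def __init__(self, channels: int, reduction_r: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        mid = _bottleneck_width(channels, reduction_r)
        self.conv_shared = Conv2d(channels, mid, 1, rng=rng)
        self.bn = BatchNorm2d(mid)
        self.act = ReLU()
        self.conv_h = Conv2d(mid, channels, 1, rng=rng)
        self.conv_w = Conv2d(mid, channels, 1, rng=rng)
        self.gate_h = Sigmoid()
        self.gate_w = Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        n, c, h, w = x.shape
        pool_h = F.mean(x, axis=3, keepdims=True)              # (N,C,H,1)
        pool_w = F.mean(x, axis=2, keepdims=True)              # (N,C,1,W)
        pool_w_t = F.transpose(pool_w, (0, 1, 3, 2))           # (N,C,W,1)
        y = F.concat([pool_h, pool_w_t], axis=2)               # (N,C,H+W,1)
        y = self.act(self.bn(self.conv_shared(y)))
        y_h = y[:, :, :h, :]                                   # (N,mid,H,1)
        y_w = F.transpose(y[:, :, h:, :], (0, 1, 3, 2))        # (N,mid,1,W)
        a_h = self.gate_h(self.conv_h(y_h))                    # (N,C,H,1)
        a_w = self.gate_w(self.conv_w(y_w))                    # (N,C,1,W)
        return x * a_h * a_w

    def own_macs(self, in_shape, out_shape):
        n, c, h, w = in_shape
        # directional pooling (1 MAC/input element each) + two gate multiplies
        return 2 * c * h * w + 2 * c * h * w


class SqueezeExcitation(Module):
    """SE gate: global average pool -> bottleneck MLP -> logistic -> rescale."""

    def __init__(self, channels: int, reduction_r: int = 4,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        mid = _bottleneck_width(channels, reduction_r)
        self.fc1 = Conv2d(channels, mid, 1, bias=True, rng=rng)
        self.act = ReLU()
        self.fc2 = Conv2d(mid, channels, 1, bias=True, rng=rng)
        self.gate = Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        s = F.mean(x, axis=(2, 3), keepdims=True)              # (N,C,1,1)
        g = self.gate(self.fc2(self.act(self.fc1(s))))
        return x * g

    def own_macs(self, in_shape, out_shape):
        n, c, h, w = in_shape
        return c * h * w + c * h * w  # squeeze pool + gate multiply


def eca_kernel_size(channels: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Adaptive ECA kernel size: nearest odd to |log2(C)/gamma + b/gamma|."""
    k = int(abs(math.log2(channels) / gamma + b / gamma))
    return k if k % 2 == 1 else k + 1


class ECAAttention(Module):
    """ECA gate: global average pool -> 1-D conv across channels -> logistic."""

    def __init__(self, channels: int, gamma: float = 2.0, b: float = 1.0,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.kernel_size = eca_kernel_size(channels, gamma, b)
        rng = rng or np.random.default_rng()
        bound = math.sqrt(1.0 / self.kernel_size)
        self.weight = Parameter(rng.uniform(-bound, bound, (self.kernel_size,)))
        self.gate = Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        n, c, h, w = x.shape
        s = F.mean(x, axis=(2, 3), keepdims=True)              # (N,C,1,1)
        # 1-D convolution across the channel axis, zero padded
        s4 = F.transpose(s, (0, 3, 1, 2))                      # (N,1,C,1)
        k = self.kernel_size
        wt = F.reshape(self.weight, (1, 1, k, 1))
        pad = (k - 1) // 2
        zeros = Tensor(np.zeros((n, 1, pad, 1), dtype=np.float32))
        s_pad = F.concat([zeros, s4, zeros], axis=2)
        y = F.conv2d(s_pad, wt)
        g = self.gate(F.transpose(y, (0, 2, 3, 1)))            # (N,C,1,1)
        return x * g

    def own_macs(self, in_shape, out_shape):
        n, c, h, w = in_shape
        return c * h * w + self.kernel_size * c + c * h * w


class _ChannelGate(Module):
    """CBAM channel gate: shared MLP over avg- and max-pooled descriptors."""

    def __init__(self, channels: int, reduction_r: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        mid = _bottleneck_width(channels, reduction_r)
        self.fc1 = Conv2d(channels, mid, 1, bias=True, rng=rng)
        self.act = ReLU()
        self.fc2 = Conv2d(mid, channels, 1, bias=True, rng=rng)
        self.gate = Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        avg = F.mean(x, axis=(2, 3), keepdims=True)
        mx = F.reshape(x, (n, c, h * w))
        mx = _channel_max(mx)
        shared = lambda s: self.fc2(self.act(self.fc1(s)))
        return self.gate(shared(avg) + shared(mx))

    def own_macs(self, in_shape, out_shape):
        n, c, h, w = in_shape
        return 2 * c * h * w + c  # two pools + descriptor sum


def _channel_max(x3: Tensor) -> Tensor:
    """Max over the last axis of (N, C, HW), returned as (N, C, 1, 1)."""
    data = x3.data
    arg = data.argmax(axis=2)
    n, c, _ = data.shape
    idx = (np.arange(n)[:, None].repeat(c, 1), np.arange(c)[None, :].repeat(n, 0), arg)
    out = x3[idx]
    return F.reshape(out, (n, c, 1, 1))


class _SpatialGate(Module):
    """CBAM spatial gate: k x k conv over stacked channel-avg and channel-max maps."""

    def __init__(self, kernel_size: int = 7, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv2d(2, 1, kernel_size, padding=kernel_size // 2, rng=rng)
        self.gate = Sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        avg = F.mean(x, axis=1, keepdims=True)                 # (N,1,H,W)
        xt = F.transpose(x, (0, 2, 3, 1))
        xt = F.reshape(xt, (n, h * w, c))
        arg = xt.data.argmax(axis=2)
        idx = (np.repeat(np.arange(n), h * w),
               np.tile(np.arange(h * w), n),
               arg.ravel())
        mx = F.reshape(xt[idx], (n, 1, h, w))
        return self.gate(self.conv(F.concat([avg, mx], axis=1)))

    def own_macs(self, in_shape, out_shape):
        n, c, h, w = in_shape
        return 2 * c * h * w


class CBAM(Module):
    """CBAM: channel gate multiplied in first, spatial gate second."""

    def __init__(self, channels: int, reduction_r: int = 4, spatial_kernel: int = 7,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.channel_gate = _ChannelGate(channels, reduction_r, rng=rng)
        self.spatial_gate = _SpatialGate(spatial_kernel, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(
                f"expected {self.channels} channels, got {x.shape[1]}")
        out = x * self.channel_gate(x)
        out = out * self.spatial_gate(out)
        return out

    def own_macs(self, in_shape, out_shape):
        n, c, h, w = in_shape
        return 2 * c * h * w  # the two gate multiplies


def build_attention(channels: int, cfg: AttentionConfig,
                    rng: np.random.Generator | None = None) -> Module:
    """Instantiate the configured attention operator for ``channels``."""
    if cfg.kind == "none":
        return Identity()
    if cfg.kind == "CA":
        return CoordinateAttention(channels, cfg.reduction_r, rng=rng)
    if cfg.kind == "SE":
        return SqueezeExcitation(channels, cfg.reduction_r, rng=rng)
    if cfg.kind == "ECA":
        return ECAAttention(channels, cfg.eca_gamma, cfg.eca_b, rng=rng)
    if cfg.kind == "CBAM":
        return CBAM(channels, cfg.reduction_r, cfg.spatial_kernel, rng=rng)
    raise ValueError(f"unknown attention kind {cfg.kind!r}")
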