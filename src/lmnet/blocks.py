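"""The three residual blocks of the network family and their sub-operators.

* :class:`CBAMDBlock` — depthwise 7x7 + 3x3 conv with CBAM gating (the
  historical first design).
* :class:`ImprovedResNetBlock` — dilated 3x3 conv followed by a four-branch
  inception unit and coordinate attention (the "R" stage type).
* :class:`SMBlock` — grouped-pointwise inverted bottleneck with depthwise
  3x3, coordinate attention and channel shuffle (the "S" stage type).
* :class:`BasicBlock` — the plain two-conv residual block ("O" stage type)
  used by the unmodified ResNet-18 topology.

Channel widths, group counts and inception branch hidden widths are
carried by :class:`BlockConfig`; the canonical values live in
:mod:`lmnet.models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attention import AttentionConfig, CBAM, build_attention
from .nn import (BatchNorm2d, Conv2d, Identity, MaxPool2d, Module, ReLU,
                 Sequential, F)
from .nn.autograd import Tensor

__all__ = [
    "BlockConfig", "channel_shuffle", "InceptionUnit", "CBAMDBlock",
    "ImprovedResNetBlock", "SMBlock", "BasicBlock",
]


@dataclass
class BlockConfig:
    """Declarative description of one residual block.

    ``branch_hidden`` is the hidden width of the 3x3 inception branch
    (branch b); ``branch_reduce`` the 1x1-reduction width feeding the
    depthwise 7x7 branch (branch c).  ``groups_g`` and ``expansion_t``
    parameterise the SM bottleneck; ``dilation`` the improved block's
    first convolution.
    """

    in_channels: int = 64
    out_channels: int = 64
    stride: int = 1
    dilation: int = 2
    branch_hidden: int = 64
    branch_reduce: int = 16
    groups_g: int = 4
    expansion_t: float = 1.0
    attention: AttentionConfig = field(default_factory=AttentionConfig)

    def __post_init__(self):
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")

    def with_(self, **kw) -> "BlockConfig":
        return replace(self, **kw)


def channel_shuffle(x: Tensor, groups: int) -> Tensor:
    """Interleave channel groups by the reshape-transpose-flatten permutation.

    With C channels in g groups the channel at index ``i`` moves to
    ``(i % (C/g)) * g + i // (C/g)``; values are untouched.
    """
    n, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channel count {c} not divisible by groups={groups}")
    if groups == 1:
        return x
    x = F.reshape(x, (n, groups, c // groups, h, w))
    x = F.transpose(x, (0, 2, 1, 3, 4))
    return F.reshape(x, (n, c, h, w))


def _downsample(cfg: BlockConfig, rng) -> Module:
    """1x1 conv + BN identity path used whenever the block changes shape."""
    if cfg.stride == 1 and cfg.in_channels == cfg.out_channels:
        return Identity()
    return Sequential(
        Conv2d(cfg.in_channels, cfg.out_channels, 1, stride=cfg.stride, rng=rng),
        BatchNorm2d(cfg.out_channels),
    )


class _ResidualBase(Module):
    """Shared residual-add plumbing; subclasses implement ``main_path``."""

    def __init__(self, cfg: BlockConfig, rng):
        super().__init__()
        self.cfg = cfg
        self.downsample = _downsample(cfg, rng)
        self.out_act = ReLU()

    def main_path(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}")
        return self.out_act(self.main_path(x) + self.downsample(x))

    def own_macs(self, in_shape, out_shape):
        return int(np.prod(out_shape[1:]))  # the residual add


class InceptionUnit(Module):
    """Four parallel branches, each emitting ``out_channels/4`` channels.

    (a) 1x1 conv; (b) 1x1 reduce to ``branch_hidden`` then 3x3 conv;
    (c) 1x1 reduce to ``branch_reduce`` then depthwise 7x7 then 1x1 to
    width; (d) 3x3 max-pool (stride 1, padded) then 1x1 conv.  Outputs are
    concatenated, restoring ``out_channels``; spatial size is unchanged.
    """

    def __init__(self, cfg: BlockConfig, rng=None):
        super().__init__()
        c = cfg.out_channels
        if c % 4:
            raise ValueError(f"out_channels {c} not divisible by 4")
        quarter = c // 4
        self.branch_a = Conv2d(c, quarter, 1, rng=rng)
        self.branch_b = Sequential(
            Conv2d(c, cfg.branch_hidden, 1, rng=rng),
            Conv2d(cfg.branch_hidden, quarter, 3, padding=1, rng=rng),
        )
        self.branch_c = Sequential(
            Conv2d(c, cfg.branch_reduce, 1, rng=rng),
            Conv2d(cfg.branch_reduce, cfg.branch_reduce, 7, padding=3,
                   groups=cfg.branch_reduce, rng=rng),
            Conv2d(cfg.branch_reduce, quarter, 1, rng=rng),
        )
        self.branch_d = Sequential(
            MaxPool2d(3, stride=1, padding=1),
            Conv2d(c, quarter, 1, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return F.concat(
            [self.branch_a(x), self.branch_b(x), self.branch_c(x), self.branch_d(x)],
            axis=1)


class CBAMDBlock(_ResidualBase):
    """Depthwise 7x7 -> BN -> ReLU -> 3x3 conv -> BN -> CBAM -> residual.

    The 7x7 depthwise convolution widens the receptive field without a
    parameter blow-up; CBAM applies its channel gate then its spatial gate
    before the residual add.
    """

    def __init__(self, cfg: BlockConfig, rng=None):
        super().__init__(cfg, rng)
        att = cfg.attention
        self.conv1 = Conv2d(cfg.in_channels, cfg.in_channels, 7, stride=cfg.stride,
                            padding=3, groups=cfg.in_channels, rng=rng)
        self.bn1 = BatchNorm2d(cfg.in_channels)
        self.act1 = ReLU()
        self.conv2 = Conv2d(cfg.in_channels, cfg.out_channels, 3, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(cfg.out_channels)
        self.cbam = CBAM(cfg.out_channels, att.reduction_r, att.spatial_kernel,
                         rng=rng)

    def main_path(self, x):
        out = self.act1(self.bn1(self.conv1(x)))
        out = self.bn2(self.conv2(out))
        return self.cbam(out)


class ImprovedResNetBlock(_ResidualBase):
    """Dilated 3x3 -> BN -> ReLU -> inception -> attention -> BN -> residual."""

    def __init__(self, cfg: BlockConfig, rng=None):
        super().__init__(cfg, rng)
        d = cfg.dilation
        self.conv1 = Conv2d(cfg.in_channels, cfg.out_channels, 3, stride=cfg.stride,
                            padding=d, dilation=d, rng=rng)
        self.bn1 = BatchNorm2d(cfg.out_channels)
        self.act1 = ReLU()
        self.inception = InceptionUnit(cfg, rng=rng)
        self.attention = build_attention(cfg.out_channels, cfg.attention, rng=rng)
        self.bn2 = BatchNorm2d(cfg.out_channels)

    def main_path(self, x):
        out = self.act1(self.bn1(self.conv1(x)))
        out = self.inception(out)
        out = self.attention(out)
        return self.bn2(out)


class SMBlock(_ResidualBase):
    """Grouped inverted bottleneck with depthwise 3x3, attention and shuffle.

    Expansion and projection are grouped pointwise convolutions (a
    depthwise 1x1 cannot change channel count); the channel shuffle after
    projection restores cross-group information flow, the ShuffleNet
    construction this block borrows.
    """

    def __init__(self, cfg: BlockConfig, rng=None):
        super().__init__(cfg, rng)
        g = cfg.groups_g
        hidden = int(round(cfg.expansion_t * cfg.in_channels))
        if hidden % g or cfg.out_channels % g:
            raise ValueError(
                f"bottleneck width {hidden} / out {cfg.out_channels} "
                f"not divisible by groups={g}")
        self.groups_g = g
        self.expand = Conv2d(cfg.in_channels, hidden, 1, groups=g, rng=rng)
        self.bn1 = BatchNorm2d(hidden)
        self.act1 = ReLU()
        self.dwconv = Conv2d(hidden, hidden, 3, stride=cfg.stride, padding=1,
                             groups=hidden, rng=rng)
        self.attention = build_attention(hidden, cfg.attention, rng=rng)
        self.bn2 = BatchNorm2d(hidden)
        self.project = Conv2d(hidden, cfg.out_channels, 1, groups=g, rng=rng)
        self.bn3 = BatchNorm2d(cfg.out_channels)

    def main_path(self, x):
        out = self.act1(self.bn1(self.expand(x)))
        out = self.dwconv(out)
        out = self.attention(out)
        out = self.bn2(out)
        out = self.bn3(self.project(out))
        return channel_shuffle(out, self.groups_g)


class BasicBlock(_ResidualBase):
    """The unmodified two-conv ResNet basic block (stage type "O")."""

    def __init__(self, cfg: BlockConfig, rng=None):
        super().__init__(cfg, rng)
        self.conv1 = Conv2d(cfg.in_channels, cfg.out_channels, 3, stride=cfg.stride,
                            padding=1, rng=rng)
        self.bn1 = BatchNorm2d(cfg.out_channels)
        self.act1 = ReLU()
        self.conv2 = Conv2d(cfg.out_channels, cfg.out_channels, 3, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(cfg.out_channels)

    def main_path(self, x):
        return self.bn2(self.conv2(self.act1(self.bn1(self.conv1(x)))))
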