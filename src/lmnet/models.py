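"""Network assembly: the LMN, its stage-type variant grid, and baselines.

The LMN ("lightweight multi-scale network") keeps the ResNet-18 skeleton
(7x7 stem, four two-block stages at widths 64/128/256/512, global average
pool head) but replaces the first two stages with the improved multi-scale
residual block ("R") and the last two with the shuffled inverted
bottleneck ("S"), both gated by coordinate attention.

``CANONICAL_DIALS`` freezes the per-stage hyperparameters the published
complexity budget pins down but the block definitions leave open
(inception branch widths, SM group counts and expansion, attention
reduction).  See docs/methods.md for how these were fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .attention import AttentionConfig
from .blocks import (BasicBlock, BlockConfig, CBAMDBlock, ImprovedResNetBlock,
                     SMBlock)
from .nn import (BatchNorm2d, Conv2d, GlobalAvgPool, Identity, Linear,
                 MaxPool2d, Module, ReLU, Sequential)
from .nn.autograd import Tensor

__all__ = [
    "StageDials", "ModelConfig", "CANONICAL_DIALS", "TINY_DIALS",
    "build_lmn", "build_variant", "build_cbamd_resnet", "build_baseline",
    "BASELINE_NAMES", "tiny_config",
]

STAGE_STRIDES = (1, 2, 2, 2)


@dataclass(frozen=True)
class StageDials:
    """Per-stage calibration hyperparameters left open by the block design."""

    reduction_r: int          # attention bottleneck reduction
    branch_hidden: int        # inception branch (b) hidden width
    branch_reduce: int        # inception branch (c) reduction width
    groups_g: int             # SM grouped-conv groups
    expansion_t: float        # SM bottleneck expansion


# Frozen by the complexity calibration against the published budget
# (1.4 M params / 1.65 GFLOPs with CA; 0.76 M / 1.63 G without).
CANONICAL_DIALS: tuple[StageDials, ...] = (
    StageDials(reduction_r=8, branch_hidden=72, branch_reduce=32, groups_g=32, expansion_t=1.0),
    StageDials(reduction_r=4, branch_hidden=160, branch_reduce=32, groups_g=32, expansion_t=1.0),
    StageDials(reduction_r=2, branch_hidden=64, branch_reduce=64, groups_g=32, expansion_t=1.0),
    StageDials(reduction_r=2, branch_hidden=128, branch_reduce=128, groups_g=16, expansion_t=1.0),
)

# Desk-scale dials for the width-reduced model used in training tests.
TINY_DIALS: tuple[StageDials, ...] = (
    StageDials(reduction_r=2, branch_hidden=8, branch_reduce=4, groups_g=2, expansion_t=2.0),
    StageDials(reduction_r=2, branch_hidden=16, branch_reduce=4, groups_g=2, expansion_t=2.0),
    StageDials(reduction_r=2, branch_hidden=16, branch_reduce=8, groups_g=2, expansion_t=2.0),
    StageDials(reduction_r=2, branch_hidden=32, branch_reduce=16, groups_g=2, expansion_t=2.0),
)


@dataclass
class ModelConfig:
    """Declarative description of one network in the family."""

    stage_types: str = "RRSS"                 # R / S / O per stage
    depths: tuple[int, ...] = (2, 2, 2, 2)
    widths: tuple[int, ...] = (64, 128, 256, 512)
    num_classes: int = 7
    attention_kind: str = "CA"                # CA | CBAM | SE | ECA | none
    dilation: int = 2
    dials: tuple[StageDials, ...] = CANONICAL_DIALS
    stem_width: int = 64
    seed: int = 0

    def __post_init__(self):
        self.stage_types = self.stage_types.upper()
        if len(self.stage_types) != 4 or set(self.stage_types) - set("RSO"):
            raise ValueError(
                f"stage_types must be four letters over R/S/O, got {self.stage_types!r}")
        if len(self.depths) != 4 or len(self.widths) != 4:
            raise ValueError("depths and widths must have length 4")
        for t, w in zip(self.stage_types, self.widths):
            if t == "R" and w % 4:
                raise ValueError(f"R-stage width {w} not divisible by 4")

    def with_(self, **kw) -> "ModelConfig":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {
            "stage_types": self.stage_types,
            "depths": list(self.depths),
            "widths": list(self.widths),
            "num_classes": self.num_classes,
            "attention_kind": self.attention_kind,
            "dilation": self.dilation,
            "dials": [vars(d).copy() for d in self.dials],
            "stem_width": self.stem_width,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "dials" in d:
            d["dials"] = tuple(StageDials(**x) for x in d["dials"])
        for key in ("depths", "widths"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


_BLOCKS = {"R": ImprovedResNetBlock, "S": SMBlock, "O": BasicBlock}


class ClassifierNet(Module):
    """Stem -> four stages -> global average pool -> linear head."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.config = cfg
        rng = np.random.default_rng(cfg.seed)
        self.stem = Sequential(
            Conv2d(3, cfg.stem_width, 7, stride=2, padding=3, rng=rng),
            BatchNorm2d(cfg.stem_width),
            ReLU(),
            MaxPool2d(3, stride=2, padding=1),
        )
        self.stages = []
        in_ch = cfg.stem_width
        for stype, depth, width, stride, dials in zip(
                cfg.stage_types, cfg.depths, cfg.widths, STAGE_STRIDES, cfg.dials):
            blocks = []
            for i in range(depth):
                att_kind = cfg.attention_kind if stype in "RS" else "none"
                bcfg = BlockConfig(
                    in_channels=in_ch if i == 0 else width,
                    out_channels=width,
                    stride=stride if i == 0 else 1,
                    dilation=cfg.dilation,
                    branch_hidden=dials.branch_hidden,
                    branch_reduce=dials.branch_reduce,
                    groups_g=dials.groups_g,
                    expansion_t=dials.expansion_t,
                    attention=AttentionConfig(kind=att_kind,
                                              reduction_r=dials.reduction_r),
                )
                blocks.append(_BLOCKS[stype](bcfg, rng=rng))
            self.stages.append(Sequential(*blocks))
            in_ch = width
        self.pool = GlobalAvgPool()
        self.head = Linear(cfg.widths[-1], cfg.num_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        out = self.stem(x)
        for stage in self.stages:
            out = stage(out)
        return self.head(self.pool(out))


def build_lmn(cfg: ModelConfig | None = None) -> ClassifierNet:
    """The canonical LMN: stage types R,R,S,S with coordinate attention."""
    cfg = cfg or ModelConfig()
    if cfg.stage_types != "RRSS":
        raise ValueError("the LMN is the RRSS variant; use build_variant for others")
    return ClassifierNet(cfg)


def build_variant(code: str, cfg: ModelConfig | None = None) -> ClassifierNet:
    """A network with the stage-type string ``code`` (e.g. "RSRS", "OOOO")."""
    base = cfg or ModelConfig()
    return ClassifierNet(base.with_(stage_types=code))


def build_cbamd_resnet(num_classes: int = 7,
                       cfg: ModelConfig | None = None) -> ClassifierNet:
    """The historical CBAMD-ResNet: every basic block swapped for a CBAMD block.

    Retained for completeness; the LMN superseded it.
    """
    base = (cfg or ModelConfig()).with_(stage_types="OOOO",
                                        num_classes=num_classes,
                                        attention_kind="CBAM")
    net = ClassifierNet.__new__(ClassifierNet)
    Module.__init__(net)
    net.config = base
    rng = np.random.default_rng(base.seed)
    net.stem = Sequential(
        Conv2d(3, base.stem_width, 7, stride=2, padding=3, rng=rng),
        BatchNorm2d(base.stem_width),
        ReLU(),
        MaxPool2d(3, stride=2, padding=1),
    )
    net.stages = []
    in_ch = base.stem_width
    for depth, width, stride, dials in zip(base.depths, base.widths,
                                           STAGE_STRIDES, base.dials):
        blocks = []
        for i in range(depth):
            bcfg = BlockConfig(
                in_channels=in_ch if i == 0 else width,
                out_channels=width,
                stride=stride if i == 0 else 1,
                attention=AttentionConfig(kind="CBAM",
                                          reduction_r=dials.reduction_r),
            )
            blocks.append(CBAMDBlock(bcfg, rng=rng))
        net.stages.append(Sequential(*blocks))
        in_ch = width
    net.pool = GlobalAvgPool()
    net.head = Linear(base.widths[-1], base.num_classes, rng=rng)
    return net


def tiny_config(num_classes: int = 4, seed: int = 0) -> ModelConfig:
    """Width-reduced LMN ([8, 16, 32, 64]) for desk-scale training."""
    return ModelConfig(widths=(8, 16, 32, 64), num_classes=num_classes,
                       dials=TINY_DIALS, stem_width=8, seed=seed)


# ---------------------------------------------------------------------
# baseline registry (standard published architectures, same framework)
# ---------------------------------------------------------------------

def _resnet(layers: tuple[int, ...], num_classes: int, seed: int = 0) -> Module:
    cfg = ModelConfig(stage_types="OOOO", depths=layers, num_classes=num_classes,
                      attention_kind="none", seed=seed)
    return ClassifierNet(cfg)


class _MBInvertedResidual(Module):
    """MobileNetV2 inverted residual (expand 1x1, dw 3x3, project 1x1)."""

    def __init__(self, inp, oup, stride, expand_ratio, rng):
        super().__init__()
        hidden = inp * expand_ratio
        self.use_res = stride == 1 and inp == oup
        layers = []
        if expand_ratio != 1:
            layers += [Conv2d(inp, hidden, 1, rng=rng), BatchNorm2d(hidden), ReLU()]
        layers += [
            Conv2d(hidden, hidden, 3, stride=stride, padding=1, groups=hidden, rng=rng),
            BatchNorm2d(hidden), ReLU(),
            Conv2d(hidden, oup, 1, rng=rng), BatchNorm2d(oup),
        ]
        self.body = Sequential(*layers)

    def forward(self, x):
        out = self.body(x)
        return out + x if self.use_res else out

    def own_macs(self, in_shape, out_shape):
        return int(np.prod(out_shape[1:])) if self.use_res else 0


class _MobileNetV2(Module):
    SETTINGS = [  # t, c, n, s
        (1, 16, 1, 1), (6, 24, 2, 2), (6, 32, 3, 2), (6, 64, 4, 2),
        (6, 96, 3, 1), (6, 160, 3, 2), (6, 320, 1, 1),
    ]

    def __init__(self, num_classes=1000, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        features = [Conv2d(3, 32, 3, stride=2, padding=1, rng=rng),
                    BatchNorm2d(32), ReLU()]
        inp = 32
        for t, c, n, s in self.SETTINGS:
            for i in range(n):
                features.append(_MBInvertedResidual(inp, c, s if i == 0 else 1, t, rng))
                inp = c
        features += [Conv2d(inp, 1280, 1, rng=rng), BatchNorm2d(1280), ReLU()]
        self.features = Sequential(*features)
        self.pool = GlobalAvgPool()
        self.classifier = Linear(1280, num_classes, rng=rng)

    def forward(self, x):
        return self.classifier(self.pool(self.features(x)))


class _ShuffleUnit(Module):
    """ShuffleNetV2 unit: channel split at stride 1, two branches at stride 2."""

    def __init__(self, inp, oup, stride, rng):
        super().__init__()
        self.stride = stride
        branch = oup // 2
        if stride == 1:
            self.branch1 = Identity()
            right_in = inp // 2
        else:
            self.branch1 = Sequential(
                Conv2d(inp, inp, 3, stride=2, padding=1, groups=inp, rng=rng),
                BatchNorm2d(inp),
                Conv2d(inp, branch, 1, rng=rng), BatchNorm2d(branch), ReLU(),
            )
            right_in = inp
        self.branch2 = Sequential(
            Conv2d(right_in, branch, 1, rng=rng), BatchNorm2d(branch), ReLU(),
            Conv2d(branch, branch, 3, stride=stride, padding=1, groups=branch, rng=rng),
            BatchNorm2d(branch),
            Conv2d(branch, branch, 1, rng=rng), BatchNorm2d(branch), ReLU(),
        )

    def forward(self, x):
        from .blocks import channel_shuffle
        from .nn import F
        if self.stride == 1:
            c = x.shape[1] // 2
            left, right = x[:, :c], x[:, c:]
            out = F.concat([left, self.branch2(right)], axis=1)
        else:
            out = F.concat([self.branch1(x), self.branch2(x)], axis=1)
        return channel_shuffle(out, 2)


class _ShuffleNetV2(Module):
    def __init__(self, stage_out, repeats=(4, 8, 4), num_classes=1000, seed=0):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.stem = Sequential(Conv2d(3, 24, 3, stride=2, padding=1, rng=rng),
                               BatchNorm2d(24), ReLU())
        self.maxpool = MaxPool2d(3, stride=2, padding=1)
        inp = 24
        self.stages = []
        for out, rep in zip(stage_out, repeats):
            units = [_ShuffleUnit(inp, out, 2, rng)]
            units += [_ShuffleUnit(out, out, 1, rng) for _ in range(rep - 1)]
            self.stages.append(Sequential(*units))
            inp = out
        self.conv5 = Sequential(Conv2d(inp, 1024, 1, rng=rng),
                                BatchNorm2d(1024), ReLU())
        self.pool = GlobalAvgPool()
        self.fc = Linear(1024, num_classes, rng=rng)

    def forward(self, x):
        out = self.maxpool(self.stem(x))
        for stage in self.stages:
            out = stage(out)
        return self.fc(self.pool(self.conv5(out)))


BASELINE_NAMES = ("resnet18", "resnet34", "mobilenet_v2",
                  "shufflenet_v2_x1_0", "shufflenet_v2_x0_5")
_UNSUPPORTED = ("resnet50", "convnext_tiny", "inceptionnext_small",
                "inceptionnext_tiny", "parcnetv2")


def build_baseline(name: str, num_classes: int = 1000, seed: int = 0) -> Module:
    """Instantiate a standard published comparison architecture by name."""
    if name == "resnet18":
        return _resnet((2, 2, 2, 2), num_classes, seed)
    if name == "resnet34":
        return _resnet((3, 4, 6, 3), num_classes, seed)
    if name == "mobilenet_v2":
        return _MobileNetV2(num_classes, seed)
    if name == "shufflenet_v2_x1_0":
        return _ShuffleNetV2((116, 232, 464), num_classes=num_classes, seed=seed)
    if name == "shufflenet_v2_x0_5":
        return _ShuffleNetV2((48, 96, 192), num_classes=num_classes, seed=seed)
    if name in _UNSUPPORTED:
        raise ValueError(f"baseline {name!r} is registered but not supported")
    raise ValueError(
        f"unknown baseline {name!r}; supported: {', '.join(BASELINE_NAMES)}")
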