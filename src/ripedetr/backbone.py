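"""ResNet-18-style feature extraction backbone with switchable partial
convolution (PConv) residual blocks.

The backbone is the "vd" flavour of ResNet-18: a three-conv stem, four
residual stages of two basic blocks each at channel widths (64, 128, 256,
512), and average-pool downsampling shortcuts.  It emits a three-level
feature pyramid S3/S4/S5 at strides 8/16/32.

A *PConv block* is a basic block whose second 3x3 convolution is a partial
convolution: only a contiguous slice of ``cp = round(r * c)`` channels is
convolved (same padding, stride 1) while the remaining ``c - cp`` channels
pass through untouched.  At the default ratio r = 1/4 this cuts that
convolution's FLOPs to 1/16 of the dense equivalent and its approximate
memory traffic to 1/4.  Only equal-channel convolutions are substituted --
the stride-2 stage-entry convolutions keep their dense form, since a
partial convolution by construction preserves the channel count.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import nn
from .nn.core import Tensor

__all__ = [
    "PConvSpec",
    "BackboneConfig",
    "FeaturePyramid",
    "PConv",
    "pconv_forward",
    "pconv_flops",
    "pconv_memory_access",
    "dense_conv_flops",
    "BasicBlock",
    "Backbone",
    "build_backbone",
]


# ---------------------------------------------------------------------------
# partial convolution: spec + analytic accounting
# ---------------------------------------------------------------------------

@dataclass
class PConvSpec:
    """Geometry of one partial convolution."""

    c: int                      # total channels
    r: float = 0.25             # convolved fraction cp/c
    k: int = 3                  # kernel size (odd)
    h: int = 1                  # operating feature-map height
    w: int = 1                  # operating feature-map width
    position: str = "first"     # which cp channels are convolved
    cp: int = field(init=False)

    def __post_init__(self):
        if self.k % 2 != 1:
            raise ValueError("PConv kernel size must be odd")
        if self.position not in ("first", "last"):
            raise ValueError("position must be 'first' or 'last'")
        self.cp = max(1, round(self.r * self.c))
        if not 1 <= self.cp <= self.c:
            raise ValueError(f"cp={self.cp} outside 1..c={self.c}")


def pconv_flops(spec: PConvSpec) -> int:
    """Multiply-accumulates of one partial convolution: h*w*k^2*cp^2.

    The doubling to FLOPs (1 MAC = 2 FLOPs) is the profiler's convention
    and is applied there, not here.
    """
    return spec.h * spec.w * spec.k ** 2 * spec.cp ** 2


def dense_conv_flops(spec: PConvSpec) -> int:
    """MACs of the dense convolution the PConv replaces (c -> c channels)."""
    return spec.h * spec.w * spec.k ** 2 * spec.c ** 2


def pconv_memory_access(spec: PConvSpec) -> Tuple[int, int]:
    """Memory accesses of a PConv: (exact, approximation).

    exact = h*w*2cp + k^2*cp^2 (feature reads/writes plus kernel weights);
    the approximation drops the weight term.  At r = 1/4 the approximate
    access is one quarter of the dense-conv figure h*w*2c.
    """
    approx = spec.h * spec.w * 2 * spec.cp
    exact = approx + spec.k ** 2 * spec.cp ** 2
    return exact, approx


class PConv(nn.Module):
    """Partial convolution layer: convolve cp channels, pass the rest."""

    def __init__(self, c: int, r: float = 0.25, k: int = 3, position: str = "first"):
        super().__init__()
        self.spec = PConvSpec(c=c, r=r, k=k, position=position)
        cp = self.spec.cp
        self.conv = nn.Conv2d(cp, cp, k, stride=1)

    def forward(self, x: Tensor) -> Tensor:
        cp, c = self.spec.cp, self.spec.c
        if x.shape[1] != c:
            raise ValueError(f"PConv built for {c} channels, got {x.shape[1]}")
        if cp == c:
            return self.conv(x)
        if self.spec.position == "first":
            head = self.conv(x[:, :cp])
            return nn.concat([head, x[:, cp:]], axis=1)
        tail = self.conv(x[:, c - cp:])
        return nn.concat([x[:, :c - cp], tail], axis=1)


def pconv_forward(x: Tensor, spec: PConvSpec, weights) -> Tensor:
    """Functional partial convolution with explicit weights (cp,cp,k,k)."""
    if spec.cp > spec.c:
        raise ValueError("cp > c")
    xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
    if xt.shape[1] != spec.c:
        raise ValueError("channel mismatch")
    wt = weights if isinstance(weights, Tensor) else Tensor(np.asarray(weights))
    pad = spec.k // 2
    if spec.cp == spec.c:
        return nn.conv2d(xt, wt, stride=1, padding=pad)
    if spec.position == "first":
        head = nn.conv2d(xt[:, :spec.cp], wt, stride=1, padding=pad)
        return nn.concat([head, xt[:, spec.cp:]], axis=1)
    tail = nn.conv2d(xt[:, spec.c - spec.cp:], wt, stride=1, padding=pad)
    return nn.concat([xt[:, :spec.c - spec.cp], tail], axis=1)


# ---------------------------------------------------------------------------
# backbone
# ---------------------------------------------------------------------------

@dataclass
class BackboneConfig:
    """The four-stage switchboard; default is the lightweight setting with
    PConv blocks in the last three stages."""

    stage_types: Tuple[str, str, str, str] = ("basic", "pconv", "pconv", "pconv")
    stage_channels: Tuple[int, int, int, int] = (64, 128, 256, 512)
    blocks_per_stage: Tuple[int, int, int, int] = (2, 2, 2, 2)
    stem_width: int = 32
    pconv_ratio: float = 0.25
    pconv_position: str = "first"

    def __post_init__(self):
        if len(self.stage_types) != 4:
            raise ValueError("exactly four stages")
        for t in self.stage_types:
            if t not in ("basic", "pconv"):
                raise ValueError(f"unknown stage type {t!r}")

    @staticmethod
    def baseline() -> "BackboneConfig":
        return BackboneConfig(stage_types=("basic",) * 4)


@dataclass
class FeaturePyramid:
    """Backbone outputs at strides 8, 16 and 32."""

    S3: Tensor
    S4: Tensor
    S5: Tensor

    def as_list(self):
        return [self.S3, self.S4, self.S5]


class BasicBlock(nn.Module):
    """Residual block; ``kind='pconv'`` swaps the second 3x3 conv for a
    partial convolution (the first conv may change channel count or stride,
    which a PConv cannot)."""

    def __init__(self, c_in: int, c_out: int, stride: int = 1, kind: str = "basic",
                 pconv_ratio: float = 0.25, pconv_position: str = "first"):
        super().__init__()
        self.conv1 = nn.Conv2d(c_in, c_out, 3, stride=stride)
        self.bn1 = nn.BatchNorm2d(c_out)
        if kind == "pconv":
            self.conv2 = PConv(c_out, r=pconv_ratio, position=pconv_position)
        else:
            self.conv2 = nn.Conv2d(c_out, c_out, 3)
        self.bn2 = nn.BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            # "vd" shortcut: 2x2 average pool then a 1x1 projection
            self.short_conv = nn.Conv2d(c_in, c_out, 1)
            self.short_bn = nn.BatchNorm2d(c_out)
            self.short_pool = stride != 1
        else:
            self.short_conv = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.conv1(x)).relu()
        y = self.bn2(self.conv2(y))
        if self.short_conv is not None:
            s = nn.avgpool2d(x, 2, 2) if self.short_pool else x
            s = self.short_bn(self.short_conv(s))
        else:
            s = x
        return (y + s).relu()


class Backbone(nn.Module):
    def __init__(self, cfg: Optional[BackboneConfig] = None):
        super().__init__()
        cfg = cfg or BackboneConfig()
        self.cfg = cfg
        w = cfg.stem_width
        self.stem = nn.Sequential(
            nn.ConvBNAct(3, w, 3, stride=2, act="relu"),
            nn.ConvBNAct(w, w, 3, act="relu"),
            nn.ConvBNAct(w, 2 * w, 3, act="relu"),
        )
        stages = []
        c_in = 2 * w
        for i, (kind, c_out, nblocks) in enumerate(
                zip(cfg.stage_types, cfg.stage_channels, cfg.blocks_per_stage)):
            blocks = []
            for b in range(nblocks):
                stride = 2 if (b == 0 and i > 0) else 1
                blocks.append(BasicBlock(c_in, c_out, stride, kind,
                                         cfg.pconv_ratio, cfg.pconv_position))
                c_in = c_out
            stages.append(nn.Sequential(*blocks))
        self.stage1, self.stage2, self.stage3, self.stage4 = stages
        self.out_channels = cfg.stage_channels[1:]

    def forward(self, x: Tensor) -> FeaturePyramid:
        if x.shape[-1] % 32 or x.shape[-2] % 32:
            raise ValueError(f"input side must be divisible by 32, got {x.shape[-2:]}")
        y = self.stem(x)
        y = nn.maxpool2d(y, 3, 2, 1)
        y = self.stage1(y)
        s3 = self.stage2(y)
        s4 = self.stage3(s3)
        s5 = self.stage4(s4)
        return FeaturePyramid(S3=s3, S4=s4, S5=s5)


def build_backbone(cfg: Optional[BackboneConfig] = None) -> Backbone:
    return Backbone(cfg)
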