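"""Cross-scale feature-fusion neck.

Four modes mirror the neck ablation grid:

  * ``ccfm`` — the baseline top-down + bottom-up fusion with CSP-style
    rep-conv fusion blocks;
  * ``slimneck`` — lateral/downsample convolutions become GSConv and the
    fusion blocks become VoVGSCSP;
  * ``ssff`` — the baseline plus a scale-sequence feature-fusion branch
    injected into the high-resolution (small-object) path;
  * ``slimneck_ssff`` — both changes together.

GSConv halves the channels through a standard convolution, runs a cheap
depthwise convolution on that half, concatenates, and interleaves the two
halves with a channel shuffle so information mixes across the split.
VoVGSCSP is a cross-stage block whose main branch runs through a
GS-bottleneck and is aggregated with a bypass by a single concatenation.
SSFF resizes the three pyramid levels to the highest resolution, stacks
them along a new scale axis, and extracts scale-sequence features with a
3x1x1 three-dimensional convolution that collapses the scale axis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import nn
from .nn.core import Tensor

__all__ = [
    "NeckConfig",
    "channel_shuffle",
    "GSConv",
    "GSBottleneck",
    "VoVGSCSP",
    "CSPRepLayer",
    "SSFF",
    "Neck",
]

NECK_MODES = ("ccfm", "slimneck", "ssff", "slimneck_ssff")


@dataclass
class NeckConfig:
    mode: str = "ccfm"
    fused_width: int = 256
    csp_hidden: int = 128          # fusion-block hidden width, baseline
    csp_blocks: int = 3
    slim_hidden: int = 256         # VoVGSCSP hidden width
    slim_hidden_hires: int = 160   # ... at the stride-8 fusion site
    ssff_kernel: int = 3
    ssff_target_level: int = 0     # anchor resolution: P3

    def __post_init__(self):
        if self.mode not in NECK_MODES:
            raise ValueError(f"unknown neck mode {self.mode!r}")

    @property
    def slim(self) -> bool:
        return self.mode in ("slimneck", "slimneck_ssff")

    @property
    def ssff(self) -> bool:
        return self.mode in ("ssff", "slimneck_ssff")


def channel_shuffle(x: Tensor, groups: int = 2) -> Tensor:
    """Fixed interleaving permutation of channels (invertible; applying the
    inverse permutation restores the input)."""
    N, C, H, W = x.shape
    if C % groups:
        raise ValueError("channels not divisible by groups")
    return (x.reshape(N, groups, C // groups, H, W)
             .transpose(0, 2, 1, 3, 4)
             .reshape(N, C, H, W))


def channel_unshuffle(x: Tensor, groups: int = 2) -> Tensor:
    N, C, H, W = x.shape
    return (x.reshape(N, C // groups, groups, H, W)
             .transpose(0, 2, 1, 3, 4)
             .reshape(N, C, H, W))


class GSConv(nn.Module):
    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1):
        super().__init__()
        if c_out % 2:
            raise ValueError("GSConv needs an even output width")
        half = c_out // 2
        self.conv = nn.ConvBNAct(c_in, half, k, stride)
        self.dw = nn.DWConvBNAct(half, 5)

    def forward(self, x: Tensor) -> Tensor:
        a = self.conv(x)
        b = self.dw(a)
        return channel_shuffle(nn.concat([a, b], axis=1))


class GSBottleneck(nn.Module):
    """Two chained GSConvs summed with a depthwise shortcut."""

    def __init__(self, c: int):
        super().__init__()
        self.gs1 = GSConv(c, c, 1)
        self.gs2 = GSConv(c, c, 3)
        self.short = nn.DWConvBNAct(c, 3, act="none")

    def forward(self, x: Tensor) -> Tensor:
        return self.gs2(self.gs1(x)) + self.short(x)


class VoVGSCSP(nn.Module):
    """One-off-aggregation cross-stage block built on GS-bottlenecks."""

    def __init__(self, c_in: int, c_out: int, hidden: Optional[int] = None):
        super().__init__()
        h = hidden or c_out // 2
        self.conv1 = nn.ConvBNAct(c_in, h, 1)
        self.conv2 = nn.ConvBNAct(c_in, h, 1)
        self.gsb = GSBottleneck(h)
        self.conv3 = nn.ConvBNAct(2 * h, c_out, 1)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv3(nn.concat([self.gsb(self.conv1(x)), self.conv2(x)], axis=1))


class RepConvBlock(nn.Module):
    """Training-form rep-style block: parallel 3x3 and 1x1 convs, summed."""

    def __init__(self, c: int):
        super().__init__()
        self.conv3 = nn.ConvBNAct(c, c, 3, act="none")
        self.conv1 = nn.ConvBNAct(c, c, 1, act="none")

    def forward(self, x: Tensor) -> Tensor:
        return (self.conv3(x) + self.conv1(x)).silu()


class CSPRepLayer(nn.Module):
    """Baseline cross-stage fusion block of the CCFM."""

    def __init__(self, c_in: int, c_out: int, hidden: int = 128, n: int = 3):
        super().__init__()
        self.conv1 = nn.ConvBNAct(c_in, hidden, 1)
        self.conv2 = nn.ConvBNAct(c_in, hidden, 1)
        self.blocks = nn.Sequential(*[RepConvBlock(hidden) for _ in range(n)])
        self.conv3 = (nn.ConvBNAct(hidden, c_out, 1)
                      if hidden != c_out else nn.Identity())

    def forward(self, x: Tensor) -> Tensor:
        return self.conv3(self.blocks(self.conv1(x)) + self.conv2(x))


class SSFF(nn.Module):
    """Scale-sequence feature fusion anchored at the P3 resolution.

    The lower-resolution maps are nearest-neighbour-resized (deterministic,
    and each level independently, so resize order is immaterial) and passed
    through per-level 1x1 projections; the anchor level, already at the
    target resolution and width, enters the stack directly.  The three maps
    are stacked on a new scale axis of depth three and fused by an unpadded
    3x1x1 3-D convolution that collapses the scale axis to depth one.
    """

    def __init__(self, width: int, kernel: int = 3):
        super().__init__()
        self.width = width
        self.proj = nn.ModuleList([nn.ConvBNAct(width, width, 1) for _ in range(2)])
        self.conv3d = ScaleConv3d(width, width, kernel)
        self.bn = nn.BatchNorm3d(width)

    def forward(self, p3: Tensor, p4: Tensor, p5: Tensor) -> Tensor:
        maps = [p3, p4, p5]
        for m in maps:
            if m.shape[1] != self.width:
                raise ValueError("SSFF inputs must share the configured width")
        target = p3.shape[2:]
        levels = [p3]
        for i, m in enumerate(maps[1:]):
            m = nn.resize_nearest2d(m, target)
            levels.append(self.proj[i](m))
        stack = nn.stack(levels, axis=2)          # (N, C, 3, H, W)
        y = self.bn(self.conv3d(stack)).silu()    # (N, C, 1, H, W)
        N, C, D, H, W = y.shape
        return y.reshape(N, C, H, W)


class ScaleConv3d(nn.Module):
    def __init__(self, c_in: int, c_out: int, kd: int = 3):
        super().__init__()
        from .nn.modules import _kaiming
        self.weight = nn.Parameter(_kaiming((c_out, c_in, kd), c_in * kd))

    def forward(self, x: Tensor) -> Tensor:
        return nn.conv3d_scale(x, self.weight)


class Neck(nn.Module):
    """Top-down + bottom-up cross-scale fusion over (S3, S4, F5)."""

    def __init__(self, cfg: Optional[NeckConfig] = None,
                 in_channels=(256, 256, 256)):
        super().__init__()
        cfg = cfg or NeckConfig()
        self.cfg = cfg
        w = cfg.fused_width
        if any(c != w for c in in_channels):
            raise ValueError("neck expects inputs already projected to fused_width")

        def lateral():
            return GSConv(w, w, 1) if cfg.slim else nn.ConvBNAct(w, w, 1)

        def downsample():
            return GSConv(w, w, 3, 2) if cfg.slim else nn.ConvBNAct(w, w, 3, 2)

        def fusion(hidden_slim):
            if cfg.slim:
                return VoVGSCSP(2 * w, w, hidden_slim)
            return CSPRepLayer(2 * w, w, cfg.csp_hidden, cfg.csp_blocks)

        self.lateral5 = lateral()
        self.fpn_p4 = fusion(cfg.slim_hidden)
        self.lateral4 = lateral()
        self.fpn_p3 = fusion(cfg.slim_hidden_hires)
        self.down_p3 = downsample()
        self.pan_p4 = fusion(cfg.slim_hidden)
        self.down_p4 = downsample()
        self.pan_p5 = fusion(cfg.slim_hidden)
        self.ssff_block = SSFF(w, cfg.ssff_kernel) if cfg.ssff else None

    def forward(self, s3: Tensor, s4: Tensor, f5: Tensor) -> List[Tensor]:
        lat5 = self.lateral5(f5)
        td4 = self.fpn_p4(nn.concat([nn.upsample_nearest2d(lat5), s4], axis=1))
        lat4 = self.lateral4(td4)
        p3 = self.fpn_p3(nn.concat([nn.upsample_nearest2d(lat4), s3], axis=1))
        if self.ssff_block is not None:
            p3 = p3 + self.ssff_block(s3, s4, f5)
        p4 = self.pan_p4(nn.concat([self.down_p3(p3), lat4], axis=1))
        p5 = self.pan_p5(nn.concat([self.down_p4(p4), lat5], axis=1))
        return [p3, p4, p5]
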