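"""Full detector assembly: backbone -> input projections -> intra-scale
encoder (AIFI) -> cross-scale neck -> decoding head.

:class:`ModelConfig` is the ablation switchboard.  The four switches of the
ablation grid map one-to-one onto

  * ``pconv_block``   — PConv residual blocks in the last three backbone
    stages;
  * ``aifi_dat``      — deformable attention in the AIFI encoder layer;
  * ``slimneck_ssff`` — GSConv/VoVGSCSP substitutions plus the SSFF branch
    in the neck;
  * ``inner_eiou``    — the Inner-EIoU box regression loss.

``build_model(cfg, seed)`` is deterministic: the same seed and config give
bit-identical parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Sequence

import numpy as np

from . import nn
from .backbone import Backbone, BackboneConfig, FeaturePyramid
from .encoder import AIFI
from .neck import Neck, NeckConfig
from .detr_head import (DetectionSet, HeadConfig, LossConfig, RTDETRHead,
                        total_loss)
from .nn.core import Tensor

__all__ = ["ModelConfig", "RipeDETR", "build_model", "RIPENESS_CLASS_NAMES"]

RIPENESS_CLASS_NAMES = ("unripe", "half_ripe", "ripe", "overripe", "rotten")


@dataclass
class ModelConfig:
    backbone: BackboneConfig = field(default_factory=BackboneConfig.baseline)
    encoder_mode: str = "mhsa"              # mhsa | dat
    encoder_heads: int = 8
    encoder_ffn: int = 1024
    offset_kernel: int = 5
    offset_range: float = 2.0
    neck: NeckConfig = field(default_factory=NeckConfig)
    head: HeadConfig = field(default_factory=HeadConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    d_model: int = 256

    @staticmethod
    def from_switches(pconv_block: bool = False, aifi_dat: bool = False,
                      slimneck_ssff: bool = False, inner_eiou: bool = False,
                      neck_mode: Optional[str] = None,
                      pconv_stages: Optional[int] = None) -> "ModelConfig":
        """Build a config from the four ablation switches.

        ``neck_mode`` optionally overrides the neck with one of its four
        modes; ``pconv_stages`` (1..4) replaces that many trailing stages.
        """
        if pconv_stages is None:
            pconv_stages = 3 if pconv_block else 0
        stage_types = tuple(
            "pconv" if i >= 4 - pconv_stages else "basic" for i in range(4))
        if neck_mode is None:
            neck_mode = "slimneck_ssff" if slimneck_ssff else "ccfm"
        return ModelConfig(
            backbone=BackboneConfig(stage_types=stage_types),
            encoder_mode="dat" if aifi_dat else "mhsa",
            neck=NeckConfig(mode=neck_mode),
            loss=LossConfig(box="inner_eiou" if inner_eiou else "giou"),
        )

    @staticmethod
    def baseline() -> "ModelConfig":
        return ModelConfig.from_switches()

    @staticmethod
    def full() -> "ModelConfig":
        """All four improvements on."""
        return ModelConfig.from_switches(True, True, True, True)

    @staticmethod
    def smoke() -> "ModelConfig":
        """Width-reduced configuration for CPU smoke runs."""
        return ModelConfig(
            backbone=BackboneConfig(stage_types=("basic", "pconv", "pconv", "pconv"),
                                    stage_channels=(16, 32, 64, 128), stem_width=8),
            encoder_heads=4, encoder_ffn=128,
            neck=NeckConfig(mode="ccfm", fused_width=64, csp_hidden=32,
                            csp_blocks=1, slim_hidden=64, slim_hidden_hires=48),
            head=HeadConfig(d_model=64, n_queries=60, depth=2, heads=4,
                            ffn_dim=128, dn_queries=32),
            d_model=64,
        )

    def to_dict(self) -> dict:
        return asdict(self)


class RipeDETR(nn.Module):
    """The configurable detector."""

    def __init__(self, cfg: Optional[ModelConfig] = None):
        super().__init__()
        cfg = cfg or ModelConfig.baseline()
        if cfg.head.d_model != cfg.d_model:
            cfg.head.d_model = cfg.d_model
        if cfg.neck.fused_width != cfg.d_model:
            cfg.neck.fused_width = cfg.d_model
        self.cfg = cfg
        D = cfg.d_model
        self.backbone = Backbone(cfg.backbone)
        c3, c4, c5 = self.backbone.out_channels
        self.proj3 = nn.Sequential(nn.Conv2d(c3, D, 1), nn.BatchNorm2d(D))
        self.proj4 = nn.Sequential(nn.Conv2d(c4, D, 1), nn.BatchNorm2d(D))
        self.proj5 = nn.Sequential(nn.Conv2d(c5, D, 1), nn.BatchNorm2d(D))
        self.aifi = AIFI(D, cfg.encoder_heads, cfg.encoder_ffn,
                         mode=cfg.encoder_mode, offset_kernel=cfg.offset_kernel,
                         offset_range=cfg.offset_range)
        self.neck = Neck(cfg.neck, (D, D, D))
        self.head = RTDETRHead(cfg.head)

    def features(self, images: Tensor) -> List[Tensor]:
        pyr: FeaturePyramid = self.backbone(images)
        s3 = self.proj3(pyr.S3)
        s4 = self.proj4(pyr.S4)
        f5 = self.aifi(self.proj5(pyr.S5))
        return self.neck(s3, s4, f5)

    def forward(self, images: Tensor, targets: Optional[Sequence[dict]] = None,
                rng: Optional[np.random.Generator] = None):
        fused = self.features(images)
        return self.head(fused, targets, rng)

    def loss(self, images: Tensor, targets: Sequence[dict],
             rng: Optional[np.random.Generator] = None):
        outputs = self.forward(images, targets, rng)
        return total_loss(outputs, targets, self.cfg.loss)

    def detect(self, images: Tensor, top: int = 300) -> List[DetectionSet]:
        """Inference: deterministic, NMS-free detection sets."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                outputs = self.forward(images)
                dets = self.head.detections(outputs, images.shape[-1], top)
        finally:
            self.train(was_training)
        return dets


def build_model(cfg: Optional[ModelConfig] = None, seed: int = 0) -> RipeDETR:
    """Deterministically build (and initialise) a detector."""
    nn.seed_all(seed)
    return RipeDETR(cfg)
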