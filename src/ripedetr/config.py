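"""Run configuration: one YAML file drives generation, training,
evaluation and profiling.

Training defaults follow the published schedule for this detector family:
batch size 4, 100 epochs, learning rate 1e-4, 640x640 images, decoupled-
weight-decay adaptive optimiser, and no mosaic augmentation.  Any override
is logged next to the run outputs so every artifact is reconstructible
from its resolved config plus seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

import yaml

from .model import ModelConfig

__all__ = ["TrainConfig", "RunConfig", "load_config", "save_resolved"]


@dataclass
class TrainConfig:
    batch_size: int = 4
    epochs: int = 100
    steps: Optional[int] = None        # overrides epochs when set
    learning_rate: float = 1e-4
    weight_decay: float = 0.0
    image_size: int = 640
    seed: int = 0
    n_images: int = 64
    dn_noise: float = 0.5


@dataclass
class RunConfig:
    """Everything a run needs: the four ablation switches + train settings."""

    pconv_block: bool = False
    aifi_dat: bool = False
    slimneck_ssff: bool = False
    inner_eiou: bool = False
    inner_ratio: float = 0.70
    preset: Optional[str] = None        # None | smoke
    train: TrainConfig = field(default_factory=TrainConfig)
    overrides: dict = field(default_factory=dict)

    def model_config(self) -> ModelConfig:
        if self.preset == "smoke":
            cfg = ModelConfig.smoke()
        else:
            cfg = ModelConfig.from_switches(
                self.pconv_block, self.aifi_dat, self.slimneck_ssff,
                self.inner_eiou)
        if self.inner_eiou:
            cfg.loss.box = "inner_eiou"
            cfg.loss.inner_ratio = self.inner_ratio
        return cfg

    def apply_preset(self) -> "RunConfig":
        """The smoke preset: 16 scenes at 320x320, 300 optimiser steps on a
        width-reduced model, raised learning rate; runs on one CPU."""
        if self.preset == "smoke":
            overrides = {"n_images": 16, "image_size": 320, "steps": 300,
                         "learning_rate": 1e-3}
            for k, v in overrides.items():
                if getattr(self.train, k) != v:
                    self.overrides[f"train.{k}"] = v
                    setattr(self.train, k, v)
        return self


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    train_raw = raw.pop("train", {})
    known = {f.name for f in fields(RunConfig)}
    bad = set(raw) - known
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")
    tknown = {f.name for f in fields(TrainConfig)}
    tbad = set(train_raw) - tknown
    if tbad:
        raise ValueError(f"unknown train config keys: {sorted(tbad)}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k != "overrides"})
    cfg.train = TrainConfig(**train_raw)
    return cfg.apply_preset()


def save_resolved(cfg: RunConfig, out_dir, extra: Optional[dict] = None) -> None:
    """Write the resolved config, seed and a structured run log."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.resolved.yaml", "w") as fh:
        yaml.safe_dump(asdict(cfg), fh)
    log = {"time": time.strftime("%Y-%m-%dT%H:%M:%S"),
           "seed": cfg.train.seed,
           "overrides": cfg.overrides}
    if extra:
        log.update(extra)
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
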