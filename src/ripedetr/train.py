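"""Training loop: AdamW on the set-prediction loss, with a JSON loss curve
and a reloadable checkpoint (weight archive + the YAML config that built
it)."""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import yaml

from . import nn
from .config import RunConfig, save_resolved
from .detr_head import total_loss
from .model import RipeDETR, build_model
from .synthetic_data import Sample, make_dataset

__all__ = ["samples_to_targets", "Trainer", "run_training", "load_checkpoint"]


def samples_to_targets(samples: Sequence[Sample]) -> List[dict]:
    """Normalised cxcywh boxes + class ids per image."""
    targets = []
    for s in samples:
        h, w = s.image.shape[:2]
        if s.boxes:
            arr = np.stack([b.as_array() for b in s.boxes])
            cxcywh = np.stack([
                (arr[:, 0] + arr[:, 2]) / 2 / w,
                (arr[:, 1] + arr[:, 3]) / 2 / h,
                (arr[:, 2] - arr[:, 0]) / w,
                (arr[:, 3] - arr[:, 1]) / h,
            ], axis=1)
            cls = np.array([b.cls for b in s.boxes], dtype=np.intp)
        else:
            cxcywh = np.zeros((0, 4))
            cls = np.zeros(0, dtype=np.intp)
        targets.append({"boxes": cxcywh, "classes": cls})
    return targets


def _to_batch(samples: Sequence[Sample]) -> nn.Tensor:
    imgs = np.stack([s.image for s in samples]).astype(np.float32) / 255.0
    return nn.Tensor(imgs.transpose(0, 3, 1, 2))


class Trainer:
    def __init__(self, model: RipeDETR, samples: Sequence[Sample],
                 lr: float = 1e-4, batch_size: int = 4, seed: int = 0,
                 weight_decay: float = 0.0):
        self.model = model
        self.samples = list(samples)
        self.targets = samples_to_targets(samples)
        self.batch_size = batch_size
        self.rng = np.random.default_rng(seed)
        self.opt = nn.AdamW(model.parameters(), lr=lr, weight_decay=weight_decay)
        self.curve: List[dict] = []

    def step(self) -> float:
        idx = self.rng.choice(len(self.samples), size=min(self.batch_size,
                                                          len(self.samples)),
                              replace=False)
        batch = _to_batch([self.samples[i] for i in idx])
        targets = [self.targets[i] for i in idx]
        loss, comps = self.model.loss(batch, targets, self.rng)
        loss.backward()
        self.opt.step()
        self.opt.zero_grad()
        value = float(loss.data)
        self.curve.append({"step": len(self.curve) + 1, "loss": value, **comps})
        return value

    def run(self, steps: int, log_every: int = 25, verbose: bool = True) -> List[dict]:
        for i in range(steps):
            value = self.step()
            if verbose and ((i + 1) % log_every == 0 or i == 0):
                print(f"step {i + 1:4d}/{steps}  loss {value:.3f}")
        return self.curve


def run_training(cfg: RunConfig, out_dir, samples: Optional[Sequence[Sample]] = None,
                 verbose: bool = True) -> dict:
    """Train per config; writes loss_curve.json, checkpoint.npz and the
    resolved config next to it.  Returns a summary dict."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tc = cfg.train
    if samples is None:
        samples = make_dataset(tc.n_images, tc.image_size, seed=tc.seed)
    model = build_model(cfg.model_config(), seed=tc.seed)
    trainer = Trainer(model, samples, lr=tc.learning_rate,
                      batch_size=tc.batch_size, seed=tc.seed,
                      weight_decay=tc.weight_decay)
    if tc.steps is not None:
        steps = tc.steps
    else:
        steps = tc.epochs * max(1, len(samples) // tc.batch_size)
    curve = trainer.run(steps, verbose=verbose)
    with open(out / "loss_curve.json", "w") as fh:
        json.dump(curve, fh)
    state = model.state_dict()
    np.savez_compressed(out / "checkpoint.npz", **state)
    with open(out / "model_config.yaml", "w") as fh:
        yaml.safe_dump(cfg.model_config().to_dict(), fh)
    first = curve[0]["loss"]
    tail = float(np.mean([c["loss"] for c in curve[-10:]]))
    summary = {"steps": steps, "first_loss": first, "final_loss": tail,
               "reduction": 1.0 - tail / first}
    save_resolved(cfg, out, extra=summary)
    return summary


def load_checkpoint(out_dir, cfg: RunConfig) -> RipeDETR:
    out = Path(out_dir)
    model = build_model(cfg.model_config(), seed=cfg.train.seed)
    state = dict(np.load(out / "checkpoint.npz"))
    model.load_state_dict(state)
    return model
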