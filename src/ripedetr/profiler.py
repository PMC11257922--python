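"""Deterministic parameter and FLOP accounting for any model configuration.

Counting convention (frozen across all configurations):

  * parameters = number of trainable scalar weights;
  * one fused multiply-add = 2 FLOPs, so GFLOPs = 2 x MACs / 1e9;
  * convolutions (dense, depthwise, the 3x1x1 scale conv), linear layers
    and attention matrix products are counted as MACs; a partial
    convolution therefore contributes exactly h*w*k^2*cp^2 MACs, with its
    pass-through channels free;
  * normalisation, activations, softmax, resizing/pooling and bilinear
    sampling are excluded.

FLOPs are measured by tracing an actual forward pass on a zero image at
the stated input size: every primitive reports its kind and MAC count to
the tracer, which attributes the work to the innermost named submodule.  A
primitive whose kind is neither in the counted set nor in the explicit
free set aborts the profile with an error — nothing is skipped silently.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import nn
from .nn import core as nn_core
from .model import ModelConfig, RipeDETR, build_model

__all__ = [
    "LayerRecord",
    "ProfileReport",
    "UncountedLayerError",
    "count_params",
    "count_flops",
    "profile_model",
    "profile_config",
    "ablation_table",
]

COUNTED_OPS = {"conv2d", "depthwise_conv2d", "conv3d", "matmul"}
FREE_OPS = {"relu", "silu", "softmax", "batch_norm", "layer_norm",
            "maxpool2d", "avgpool2d", "resize", "grid_sample"}


class UncountedLayerError(RuntimeError):
    """A primitive of unknown kind ran during profiling."""


@dataclass
class LayerRecord:
    name: str
    kind: str
    params: int
    macs: int


@dataclass
class ProfileReport:
    """Per-layer and total accounting at a stated input size."""

    input_size: int
    layers: List[LayerRecord] = field(default_factory=list)
    total_params: int = 0
    total_macs: int = 0

    @property
    def params_m(self) -> float:
        """Parameters in millions (tables print two decimals)."""
        return self.total_params / 1e6

    @property
    def gflops(self) -> float:
        return 2.0 * self.total_macs / 1e9

    def summary(self) -> str:
        return (f"input {self.input_size}x{self.input_size}: "
                f"{self.params_m:.2f} M params, {self.gflops:.1f} GFLOPs")

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "params": self.total_params,
            "params_m": round(self.params_m, 2),
            "gflops": round(self.gflops, 1),
            "macs": self.total_macs,
            "layers": [vars(r) for r in self.layers],
        }


def count_params(model: nn.Module) -> int:
    """Number of trainable scalar weights."""
    return model.num_params()


class _Tracer:
    def __init__(self, model: nn.Module):
        self.names = {id(m): name for name, m in model.named_modules()}
        self.stack: List[str] = []
        self.macs: Dict[str, int] = {}
        self.kinds: Dict[str, str] = {}

    def enter(self, module) -> None:
        self.stack.append(self.names.get(id(module), type(module).__name__))

    def exit(self, module) -> None:
        self.stack.pop()

    def record(self, op: str, macs: int) -> None:
        if op not in COUNTED_OPS:
            if op in FREE_OPS:
                return
            raise UncountedLayerError(
                f"primitive {op!r} has no counting rule (free ops must be "
                f"declared explicitly)")
        scope = self.stack[-1] if self.stack else "<top>"
        self.macs[scope] = self.macs.get(scope, 0) + macs
        prev = self.kinds.get(scope)
        self.kinds[scope] = op if prev in (None, op) else "mixed"


def count_flops(model: nn.Module, input_size: int = 640,
                batch: int = 1) -> ProfileReport:
    """Trace a zero-image forward pass and account every counted primitive.

    The model is run in inference mode; the decoding head runs its full
    query-selection + decoder pipeline.
    """
    if input_size % 32:
        raise ValueError("input_size must be divisible by 32")
    tracer = _Tracer(model)
    was_training = model.training
    model.eval()
    nn.set_scope_callbacks(tracer.enter, tracer.exit)
    nn_core.set_profile_callback(tracer.record)
    try:
        with nn.no_grad():
            x = nn.Tensor(np.zeros((batch, 3, input_size, input_size), dtype=np.float32))
            model(x)
    finally:
        nn_core.set_profile_callback(None)
        nn.set_scope_callbacks(None, None)
        model.train(was_training)

    own_params: Dict[str, int] = {}
    for name, mod in model.named_modules():
        p = sum(v.size for v in mod._params.values())
        if p:
            own_params[name] = p
    report = ProfileReport(input_size=input_size)
    for name in sorted(set(tracer.macs) | set(own_params)):
        report.layers.append(LayerRecord(
            name=name,
            kind=tracer.kinds.get(name, "params-only"),
            params=own_params.get(name, 0),
            macs=tracer.macs.get(name, 0) // batch,
        ))
    report.total_params = sum(r.params for r in report.layers)
    report.total_macs = sum(r.macs for r in report.layers)
    return report


def profile_model(model: nn.Module, input_size: int = 640) -> ProfileReport:
    return count_flops(model, input_size)


def profile_config(cfg: ModelConfig, input_size: int = 640,
                   seed: int = 0) -> ProfileReport:
    """Build a model from ``cfg`` and profile it (accounting depends only
    on the architecture, not on the weights or the seed)."""
    model = build_model(cfg, seed=seed)
    return count_flops(model, input_size)


def ablation_table(configs: Sequence[tuple], input_size: int = 640,
                   fmt: str = "markdown") -> str:
    """Profile a list of ``(label, ModelConfig)`` pairs into a comparison
    table (markdown or CSV) of parameters and GFLOPs."""
    rows = []
    for label, cfg in configs:
        rep = profile_config(cfg, input_size)
        rows.append((label, f"{rep.params_m:.2f}", f"{rep.gflops:.1f}"))
    header = ("model", "Params(M)", "GFLOPs(G)")
    if fmt == "csv":
        buf = io.StringIO()
        writer = csv.writer(buf)
        writer.writerow(header)
        writer.writerows(rows)
        return buf.getvalue()
    lines = ["| " + " | ".join(header) + " |",
             "|" + "|".join(["---"] * len(header)) + "|"]
    for r in rows:
        lines.append("| " + " | ".join(r) + " |")
    return "\n".join(lines) + "\n"
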