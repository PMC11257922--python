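"""Neural-network building blocks on top of :mod:`ripedetr.nn.core`.

Construction is deterministic: call :func:`seed_all` before building a model
and every parameter is initialised from one global generator in
construction order.
"""

from __future__ import annotations

from typing import Iterator, Optional

import numpy as np

from . import core
from .core import Tensor

_RNG = np.random.default_rng(0)

# callbacks installed by the profiler to attribute work to named submodules
_SCOPE_ENTER = None
_SCOPE_EXIT = None


def seed_all(seed: int) -> None:
    """Reset the global parameter-initialisation generator."""
    global _RNG
    _RNG = np.random.default_rng(seed)


def set_scope_callbacks(enter, exit_) -> None:
    global _SCOPE_ENTER, _SCOPE_EXIT
    _SCOPE_ENTER, _SCOPE_EXIT = enter, exit_


def _kaiming(shape, fan_in: int, dtype=np.float32) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (_RNG.standard_normal(shape) * std).astype(dtype)


def _uniform(shape, bound: float, dtype=np.float32) -> np.ndarray:
    return (_RNG.uniform(-bound, bound, size=shape)).astype(dtype)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)
        # parameters stay grad-enabled even if constructed inside no_grad()
        self.requires_grad = True


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ----------------------------------------------------------
    def named_modules(self, prefix: str = "") -> Iterator[tuple]:
        yield prefix or "model", self
        for name, child in self._children.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_modules(sub)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple]:
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, child in self._children.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from child.named_parameters(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_params(self) -> int:
        """Number of trainable scalar weights."""
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        out = {}
        for name, p in self.named_parameters():
            out[name] = p.data
        for mname, mod in self.named_modules():
            for bname, buf in mod._buffers.items():
                out[f"{mname}.buffers.{bname}"] = buf
        return out

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=p.data.dtype)
        for mname, mod in self.named_modules():
            for bname in mod._buffers:
                key = f"{mname}.buffers.{bname}"
                if key in state:
                    arr = np.asarray(state[key])
                    mod._buffers[bname][...] = arr
    # -- mode ---------------------------------------------------------------
    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    # -- forward ------------------------------------------------------------
    def __call__(self, *args, **kwargs):
        if _SCOPE_ENTER is not None:
            _SCOPE_ENTER(self)
            try:
                return self.forward(*args, **kwargs)
            finally:
                _SCOPE_EXIT(self)
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, mod: Module):
        self._children[str(len(self._list))] = mod
        self._list.append(mod)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(self._list):
            self._children[str(i)] = m

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        bound = 1.0 / np.sqrt(in_features)
        self.weight = Parameter(_uniform((in_features, out_features), bound))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    def __init__(self, num: int, dim: int):
        super().__init__()
        self.weight = Parameter((_RNG.standard_normal((num, dim)) * 0.02).astype(np.float32))

    def forward(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 padding: Optional[int] = None, bias: bool = False):
        super().__init__()
        self.stride = stride
        self.padding = (k // 2) if padding is None else padding
        self.weight = Parameter(_kaiming((c_out, c_in, k, k), c_in * k * k))
        self.bias = Parameter(np.zeros(c_out, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return core.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, c: int, k: int = 3, stride: int = 1, padding: Optional[int] = None,
                 bias: bool = False):
        super().__init__()
        self.stride = stride
        self.padding = (k // 2) if padding is None else padding
        self.weight = Parameter(_kaiming((c, k, k), k * k))
        self.bias = Parameter(np.zeros(c, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return core.depthwise_conv2d(x, self.weight, self.bias,
                                     stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.weight = Parameter(np.ones(c, dtype=np.float32))
        self.bias = Parameter(np.zeros(c, dtype=np.float32))
        self.register_buffer("running_mean", np.zeros(c, dtype=np.float32))
        self.register_buffer("running_var", np.ones(c, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return core.batch_norm(x, self.weight, self.bias, self.running_mean,
                               self.running_var, self.training and core.is_grad_enabled(),
                               self.momentum, self.eps)


class BatchNorm3d(BatchNorm2d):
    """Batch norm over an (N,C,D,H,W) tensor, normalising per channel."""

    def forward(self, x: Tensor) -> Tensor:
        N, C, D, H, W = x.shape
        flat = x.transpose(0, 2, 1, 3, 4).reshape(N * D, C, H, W)
        y = super().forward(flat)
        return y.reshape(N, D, C, H, W).transpose(0, 2, 1, 3, 4)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Parameter(np.ones(d, dtype=np.float32))
        self.bias = Parameter(np.zeros(d, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return core.layer_norm(x, self.weight, self.bias, self.eps)


class ConvBNAct(Module):
    """Conv -> BatchNorm -> activation, the workhorse block of the family."""

    def __init__(self, c_in: int, c_out: int, k: int = 1, stride: int = 1,
                 act: str = "silu", padding: Optional[int] = None):
        super().__init__()
        self.conv = Conv2d(c_in, c_out, k, stride, padding)
        self.bn = BatchNorm2d(c_out)
        self.act = {"silu": SiLU(), "relu": ReLU(), "none": Identity()}[act]

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class DWConvBNAct(Module):
    def __init__(self, c: int, k: int = 3, stride: int = 1, act: str = "silu"):
        super().__init__()
        self.conv = DepthwiseConv2d(c, k, stride)
        self.bn = BatchNorm2d(c)
        self.act = {"silu": SiLU(), "relu": ReLU(), "none": Identity()}[act]

    def forward(self, x: Tensor) -> Tensor:
        return self.act(self.bn(self.conv(x)))


class MLP(Module):
    """Stack of linear layers with ReLU between (DETR-style head)."""

    def __init__(self, dims: list):
        super().__init__()
        self.layers = ModuleList([Linear(a, b) for a, b in zip(dims[:-1], dims[1:])])

    def forward(self, x: Tensor) -> Tensor:
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.wd:
                p.data *= 1 - self.lr * self.wd
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
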