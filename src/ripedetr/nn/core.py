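"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it
so that ``backward()`` can propagate gradients through the tape.  The op set
is exactly what the detector family needs: elementwise arithmetic, matmul,
convolutions (dense, depthwise and a 3x1x1 scale-axis 3-D conv), pooling,
nearest-neighbour upsampling, bilinear grid sampling, batch/layer
normalisation and the usual activations/softmax.

Every primitive reports itself to an optional profiling callback (see
:mod:`ripedetr.profiler`) together with its multiply-accumulate count; ops
that the accounting convention treats as free report zero MACs.
"""

from __future__ import annotations

import contextlib
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "is_grad_enabled",
    "concat",
    "stack",
    "conv2d",
    "depthwise_conv2d",
    "conv3d_scale",
    "maxpool2d",
    "avgpool2d",
    "upsample_nearest2d",
    "grid_sample",
    "batch_norm",
    "layer_norm",
    "softmax",
    "log_softmax",
]

_GRAD_ENABLED = True

# Profiling callback: fn(op_name: str, macs: int).  Installed by the profiler
# while tracing a forward pass; None otherwise.
_PROFILE_CB: Optional[Callable[[str, int], None]] = None


def _report(op: str, macs: int) -> None:
    if _PROFILE_CB is not None:
        _PROFILE_CB(op, int(macs))


def set_profile_callback(cb: Optional[Callable[[str, int], None]]) -> None:
    global _PROFILE_CB
    _PROFILE_CB = cb


def is_grad_enabled() -> bool:
    return _GRAD_ENABLED


@contextlib.contextmanager
def no_grad():
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def _stable_sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        if isinstance(data, Tensor):
            data = data.data
        self.data = np.asarray(data)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward: Optional[Callable[[np.ndarray], None]] = None
        self._prev: tuple = ()

    # -- construction helper ------------------------------------------------
    @staticmethod
    def _op(data: np.ndarray, parents: Sequence["Tensor"],
            backward: Callable[[np.ndarray], None]) -> "Tensor":
        out = Tensor(data)
        if _GRAD_ENABLED and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        g = np.asarray(g, dtype=self.data.dtype)
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    # -- basic properties ---------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    @property
    def dtype(self):
        return self.data.dtype

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self):
        return f"Tensor(shape={self.shape}, dtype={self.dtype}, grad={self.requires_grad})"

    def __len__(self):
        return len(self.data)

    # -- autograd driver ----------------------------------------------------
    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative DFS post-order (graphs get deep for 300 training steps)
        visiting: list[tuple[Tensor, int]] = [(self, 0)]
        visiting.pop()
        stack = [(self, iter(self._prev))]
        seen.add(id(self))
        while stack:
            node, it = stack[-1]
            advanced = False
            for child in it:
                if id(child) not in seen:
                    seen.add(id(child))
                    stack.append((child, iter(child._prev)))
                    advanced = True
                    break
            if not advanced:
                topo.append(node)
                stack.pop()
        self._accum(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # free intermediate grads/tape as we go
                node._backward = None
                node._prev = ()
                if node is not self:
                    node.grad = None

    # -- arithmetic ---------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return Tensor._op(a.data + b.data, (a, b), back)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def back(g):
            a._accum(-g)

        return Tensor._op(-a.data, (a,), back)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._op(a.data * b.data, (a, b), back)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data * b.data), b.data.shape))

        return Tensor._op(a.data / b.data, (a, b), back)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, p: float):
        a = self

        def back(g):
            a._accum(g * p * np.power(a.data, p - 1))

        return Tensor._op(np.power(a.data, p), (a,), back)

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other
        out = a.data @ b.data
        inner = a.data.shape[-1]
        _report("matmul", out.size * inner)

        def back(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.data.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.data.shape))

        return Tensor._op(out, (a, b), back)

    # -- elementwise functions ----------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def back(g):
            a._accum(g * out_data)

        return Tensor._op(out_data, (a,), back)

    def log(self):
        a = self

        def back(g):
            a._accum(g / a.data)

        return Tensor._op(np.log(a.data), (a,), back)

    def sqrt(self):
        a = self
        out_data = np.sqrt(a.data)

        def back(g):
            a._accum(g / (2.0 * out_data))

        return Tensor._op(out_data, (a,), back)

    def abs(self):
        a = self

        def back(g):
            a._accum(g * np.sign(a.data))

        return Tensor._op(np.abs(a.data), (a,), back)

    def sigmoid(self):
        a = self
        s = _stable_sigmoid(a.data)

        def back(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._op(s, (a,), back)

    def relu(self):
        a = self
        _report("relu", 0)
        mask = a.data > 0

        def back(g):
            a._accum(g * mask)

        return Tensor._op(a.data * mask, (a,), back)

    def silu(self):
        a = self
        _report("silu", 0)
        s = _stable_sigmoid(a.data)

        def back(g):
            a._accum(g * (s + a.data * s * (1.0 - s)))

        return Tensor._op(a.data * s, (a,), back)

    def clamp(self, lo=None, hi=None):
        a = self
        out_data = np.clip(a.data, lo, hi)
        mask = np.ones_like(a.data, dtype=bool)
        if lo is not None:
            mask &= a.data >= lo
        if hi is not None:
            mask &= a.data <= hi

        def back(g):
            a._accum(g * mask)

        return Tensor._op(out_data, (a,), back)

    def maximum(self, other):
        other = self._wrap(other)
        a, b = self, other
        amax = a.data >= b.data

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * amax, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~amax), b.data.shape))

        return Tensor._op(np.maximum(a.data, b.data), (a, b), back)

    def minimum(self, other):
        other = self._wrap(other)
        a, b = self, other
        amin = a.data <= b.data

        def back(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * amin, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * (~amin), b.data.shape))

        return Tensor._op(np.minimum(a.data, b.data), (a, b), back)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape))
            else:
                axes = axis if isinstance(axis, tuple) else (axis,)
                if not keepdims:
                    g = np.expand_dims(g, axes)
                a._accum(np.broadcast_to(g, a.data.shape))

        return Tensor._op(out, (a,), back)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis: int, keepdims: bool = False):
        a = self
        out = a.data.max(axis=axis, keepdims=keepdims)
        arg = a.data.argmax(axis=axis)

        def back(g):
            ga = np.zeros_like(a.data)
            gg = g if keepdims else np.expand_dims(g, axis)
            np.put_along_axis(ga, np.expand_dims(arg, axis), gg, axis)
            a._accum(ga)

        return Tensor._op(out, (a,), back)

    # -- shape ops ----------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        orig = a.data.shape

        def back(g):
            a._accum(g.reshape(orig))

        return Tensor._op(a.data.reshape(shape), (a,), back)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        a = self
        inv = np.argsort(axes)

        def back(g):
            a._accum(g.transpose(inv))

        return Tensor._op(a.data.transpose(axes), (a,), back)

    def __getitem__(self, idx):
        a = self

        def back(g):
            ga = np.zeros_like(a.data)
            np.add.at(ga, idx, g)
            a._accum(ga)

        return Tensor._op(a.data[idx], (a,), back)


# ---------------------------------------------------------------------------
# free functions
# ---------------------------------------------------------------------------

def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._op(data, tensors, back)


def stack(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def back(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, i, axis=axis))

    return Tensor._op(data, tensors, back)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = x
    _report("softmax", 0)
    m = a.data.max(axis=axis, keepdims=True)
    e = np.exp(a.data - m)
    s = e / e.sum(axis=axis, keepdims=True)

    def back(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        a._accum(s * (g - dot))

    return Tensor._op(s, (a,), back)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    a = x
    m = a.data.max(axis=axis, keepdims=True)
    z = a.data - m
    lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
    out = z - lse
    sm = np.exp(out)

    def back(g):
        a._accum(g - sm * g.sum(axis=axis, keepdims=True))

    return Tensor._op(out, (a,), back)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _pad_hw(x: np.ndarray, p: int) -> np.ndarray:
    if p == 0:
        return x
    pads = [(0, 0)] * (x.ndim - 2) + [(p, p), (p, p)]
    return np.pad(x, pads)


def conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """Dense 2-D convolution (cross-correlation), NCHW x (Co,Ci,kh,kw)."""
    xt, wt = Tensor._wrap(x), Tensor._wrap(w)
    N, C, H, W = xt.data.shape
    Co, Ci, kh, kw = wt.data.shape
    if Ci != C:
        raise ValueError(f"conv2d: input has {C} channels, weight expects {Ci}")
    OH = (H + 2 * padding - kh) // stride + 1
    OW = (W + 2 * padding - kw) // stride + 1
    xp = _pad_hw(xt.data, padding)
    out = np.zeros((N, Co, OH, OW), dtype=xt.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride]
            # (Co,Ci) . (N,Ci,OH,OW) -> (Co,N,OH,OW)
            out += np.tensordot(wt.data[:, :, ki, kj], xs, axes=([1], [1])).transpose(1, 0, 2, 3)
    if b is not None:
        bt = Tensor._wrap(b)
        out += bt.data.reshape(1, Co, 1, 1)
    else:
        bt = None
    _report("conv2d", N * Co * Ci * kh * kw * OH * OW)

    parents = [xt, wt] + ([bt] if bt is not None else [])

    def back(g):
        if bt is not None and bt.requires_grad:
            bt._accum(g.sum(axis=(0, 2, 3)))
        if wt.requires_grad:
            gw = np.zeros_like(wt.data)
            for ki in range(kh):
                for kj in range(kw):
                    xs = xp[:, :, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride]
                    gw[:, :, ki, kj] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
            wt._accum(gw)
        if xt.requires_grad:
            gxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    # (Ci,Co) . (N,Co,OH,OW) -> (Ci,N,OH,OW)
                    gs = np.tensordot(wt.data[:, :, ki, kj], g, axes=([0], [1])).transpose(1, 0, 2, 3)
                    gxp[:, :, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride] += gs
            if padding:
                gxp = gxp[:, :, padding:padding + H, padding:padding + W]
            xt._accum(gxp)

    return Tensor._op(out, parents, back)


def depthwise_conv2d(x: Tensor, w: Tensor, b: Optional[Tensor] = None,
                     stride: int = 1, padding: int = 0) -> Tensor:
    """Depthwise 2-D convolution; weight shape (C, kh, kw)."""
    xt, wt = Tensor._wrap(x), Tensor._wrap(w)
    N, C, H, W = xt.data.shape
    Cw, kh, kw = wt.data.shape
    if Cw != C:
        raise ValueError("depthwise_conv2d: channel mismatch")
    OH = (H + 2 * padding - kh) // stride + 1
    OW = (W + 2 * padding - kw) // stride + 1
    xp = _pad_hw(xt.data, padding)
    out = np.zeros((N, C, OH, OW), dtype=xt.data.dtype)
    for ki in range(kh):
        for kj in range(kw):
            xs = xp[:, :, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride]
            out += wt.data[None, :, ki, kj, None, None] * xs
    if b is not None:
        bt = Tensor._wrap(b)
        out += bt.data.reshape(1, C, 1, 1)
    else:
        bt = None
    _report("depthwise_conv2d", N * C * kh * kw * OH * OW)

    parents = [xt, wt] + ([bt] if bt is not None else [])

    def back(g):
        if bt is not None and bt.requires_grad:
            bt._accum(g.sum(axis=(0, 2, 3)))
        if wt.requires_grad:
            gw = np.zeros_like(wt.data)
            for ki in range(kh):
                for kj in range(kw):
                    xs = xp[:, :, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride]
                    gw[:, ki, kj] = (g * xs).sum(axis=(0, 2, 3))
            wt._accum(gw)
        if xt.requires_grad:
            gxp = np.zeros_like(xp)
            for ki in range(kh):
                for kj in range(kw):
                    gxp[:, :, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride] += (
                        wt.data[None, :, ki, kj, None, None] * g)
            if padding:
                gxp = gxp[:, :, padding:padding + H, padding:padding + W]
            xt._accum(gxp)

    return Tensor._op(out, parents, back)


def conv3d_scale(x: Tensor, w: Tensor, b: Optional[Tensor] = None) -> Tensor:
    """3-D convolution with a (kd,1,1) kernel over the scale axis, no padding.

    x: (N, C, D, H, W); w: (Co, Ci, kd).  Output depth is D-kd+1 — with the
    canonical 3-level stack and kd=3 the scale axis collapses to depth 1.
    """
    xt, wt = Tensor._wrap(x), Tensor._wrap(w)
    N, C, D, H, W = xt.data.shape
    Co, Ci, kd = wt.data.shape
    if Ci != C:
        raise ValueError("conv3d_scale: channel mismatch")
    OD = D - kd + 1
    if OD < 1:
        raise ValueError("conv3d_scale: scale axis shorter than kernel")
    out = np.zeros((N, Co, OD, H, W), dtype=xt.data.dtype)
    for d in range(kd):
        for od in range(OD):
            out[:, :, od] += np.tensordot(
                wt.data[:, :, d], xt.data[:, :, od + d], axes=([1], [1])).transpose(1, 0, 2, 3)
    if b is not None:
        bt = Tensor._wrap(b)
        out += bt.data.reshape(1, Co, 1, 1, 1)
    else:
        bt = None
    _report("conv3d", N * Co * Ci * kd * OD * H * W)

    parents = [xt, wt] + ([bt] if bt is not None else [])

    def back(g):
        if bt is not None and bt.requires_grad:
            bt._accum(g.sum(axis=(0, 2, 3, 4)))
        if wt.requires_grad:
            gw = np.zeros_like(wt.data)
            for d in range(kd):
                for od in range(OD):
                    gw[:, :, d] += np.tensordot(
                        g[:, :, od], xt.data[:, :, od + d], axes=([0, 2, 3], [0, 2, 3]))
            wt._accum(gw)
        if xt.requires_grad:
            gx = np.zeros_like(xt.data)
            for d in range(kd):
                for od in range(OD):
                    gx[:, :, od + d] += np.tensordot(
                        wt.data[:, :, d], g[:, :, od], axes=([0], [1])).transpose(1, 0, 2, 3)
            xt._accum(gx)

    return Tensor._op(out, parents, back)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def maxpool2d(x: Tensor, kernel: int = 3, stride: int = 2, padding: int = 1) -> Tensor:
    xt = Tensor._wrap(x)
    _report("maxpool2d", 0)
    N, C, H, W = xt.data.shape
    OH = (H + 2 * padding - kernel) // stride + 1
    OW = (W + 2 * padding - kernel) // stride + 1
    xp = _pad_hw(xt.data, padding)
    if padding:
        fill = np.finfo(xt.data.dtype).min if np.issubdtype(xt.data.dtype, np.floating) else np.iinfo(xt.data.dtype).min
        xp = xp.copy()
        xp[:, :, :padding, :] = fill
        xp[:, :, -padding:, :] = fill
        xp[:, :, :, :padding] = fill
        xp[:, :, :, -padding:] = fill
    windows = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    windows = windows[:, :, ::stride, ::stride]  # N,C,OH,OW,k,k
    flat = windows.reshape(N, C, OH, OW, kernel * kernel)
    arg = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    def back(g):
        gxp = np.zeros((N, C, H + 2 * padding, W + 2 * padding), dtype=xt.data.dtype)
        oi, oj = np.meshgrid(np.arange(OH), np.arange(OW), indexing="ij")
        ii = oi * stride + arg // kernel  # N,C,OH,OW via broadcasting
        jj = oj * stride + arg % kernel
        nn, cc = np.meshgrid(np.arange(N), np.arange(C), indexing="ij")
        nn = nn[:, :, None, None]
        cc = cc[:, :, None, None]
        np.add.at(gxp, (nn, cc, ii, jj), g)
        if padding:
            gxp = gxp[:, :, padding:padding + H, padding:padding + W]
        xt._accum(gxp)

    return Tensor._op(out, (xt,), back)


def avgpool2d(x: Tensor, kernel: int = 2, stride: int = 2) -> Tensor:
    xt = Tensor._wrap(x)
    _report("avgpool2d", 0)
    N, C, H, W = xt.data.shape
    OH, OW = (H - kernel) // stride + 1, (W - kernel) // stride + 1
    out = np.zeros((N, C, OH, OW), dtype=xt.data.dtype)
    for ki in range(kernel):
        for kj in range(kernel):
            out += xt.data[:, :, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride]
    out /= kernel * kernel

    def back(g):
        gx = np.zeros_like(xt.data)
        gs = g / (kernel * kernel)
        for ki in range(kernel):
            for kj in range(kernel):
                gx[:, :, ki:ki + stride * OH:stride, kj:kj + stride * OW:stride] += gs
        xt._accum(gx)

    return Tensor._op(out, (xt,), back)


def upsample_nearest2d(x: Tensor, scale: int = 2) -> Tensor:
    xt = Tensor._wrap(x)
    _report("resize", 0)
    out = xt.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def back(g):
        N, C, H, W = xt.data.shape
        gx = g.reshape(N, C, H, scale, W, scale).sum(axis=(3, 5))
        xt._accum(gx)

    return Tensor._op(out, (xt,), back)


def resize_nearest2d(x: Tensor, out_hw: tuple) -> Tensor:
    """Nearest-neighbour resize to an arbitrary (OH, OW)."""
    xt = Tensor._wrap(x)
    _report("resize", 0)
    N, C, H, W = xt.data.shape
    OH, OW = out_hw
    ri = (np.arange(OH) * H // OH).astype(np.intp)
    rj = (np.arange(OW) * W // OW).astype(np.intp)
    out = xt.data[:, :, ri][:, :, :, rj]

    def back(g):
        gx = np.zeros_like(xt.data)
        np.add.at(gx, (slice(None), slice(None), ri[:, None], rj[None, :]), g)
        xt._accum(gx)

    return Tensor._op(out, (xt,), back)


def grid_sample(x: Tensor, grid: Tensor) -> Tensor:
    """Bilinear sampling of ``x`` (N,C,H,W) at ``grid`` (N,P,2) points.

    Grid coordinates are normalised to [-1, 1] spanning the pixel *edges*,
    so the centre of pixel ``i`` along an axis of length ``W`` sits at
    ``(2i+1)/W - 1``; out-of-range points are clamped to the border.  Grid
    layout is (gx, gy) i.e. (width, height) order.  Differentiable in both
    the features and the sampling locations.
    """
    xt, gt = Tensor._wrap(x), Tensor._wrap(grid)
    _report("grid_sample", 0)
    N, C, H, W = xt.data.shape
    _, P, _ = gt.data.shape
    px = (gt.data[..., 0] + 1.0) * 0.5 * W - 0.5
    py = (gt.data[..., 1] + 1.0) * 0.5 * H - 0.5
    px = np.clip(px, 0.0, W - 1)
    py = np.clip(py, 0.0, H - 1)
    x0 = np.floor(px).astype(np.intp)
    y0 = np.floor(py).astype(np.intp)
    x1 = np.minimum(x0 + 1, W - 1)
    y1 = np.minimum(y0 + 1, H - 1)
    fx = px - x0
    fy = py - y0
    nn = np.arange(N)[:, None]
    v00 = xt.data[nn, :, y0, x0]  # (N,P,C)
    v01 = xt.data[nn, :, y0, x1]
    v10 = xt.data[nn, :, y1, x0]
    v11 = xt.data[nn, :, y1, x1]
    w00 = ((1 - fx) * (1 - fy))[..., None]
    w01 = (fx * (1 - fy))[..., None]
    w10 = ((1 - fx) * fy)[..., None]
    w11 = (fx * fy)[..., None]
    out = (w00 * v00 + w01 * v01 + w10 * v10 + w11 * v11).transpose(0, 2, 1)  # N,C,P

    def back(g):
        gp = g.transpose(0, 2, 1)  # N,P,C
        if xt.requires_grad:
            gx = np.zeros_like(xt.data)
            np.add.at(gx, (nn, slice(None), y0, x0), gp * w00)
            np.add.at(gx, (nn, slice(None), y0, x1), gp * w01)
            np.add.at(gx, (nn, slice(None), y1, x0), gp * w10)
            np.add.at(gx, (nn, slice(None), y1, x1), gp * w11)
            xt._accum(gx)
        if gt.requires_grad:
            # d out / d fx etc.; chain to normalised coords, zero where clamped
            dfx = ((v01 - v00) * (1 - fy)[..., None] + (v11 - v10) * fy[..., None])
            dfy = ((v10 - v00) * (1 - fx)[..., None] + (v11 - v01) * fx[..., None])
            gpx = (gp * dfx).sum(axis=-1) * 0.5 * W
            gpy = (gp * dfy).sum(axis=-1) * 0.5 * H
            inx = (px > 0) & (px < W - 1)
            iny = (py > 0) & (py < H - 1)
            gg = np.stack([gpx * inx, gpy * iny], axis=-1)
            gt._accum(gg)

    return Tensor._op(out, (xt, gt), back)


# ---------------------------------------------------------------------------
# normalisation
# ---------------------------------------------------------------------------

def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               running_mean: np.ndarray, running_var: np.ndarray,
               training: bool, momentum: float = 0.1, eps: float = 1e-5) -> Tensor:
    """Batch normalisation over (N,H,W) of an NCHW tensor (or (N,) of NC)."""
    xt = Tensor._wrap(x)
    _report("batch_norm", 0)
    axes = (0, 2, 3) if xt.data.ndim == 4 else (0,)
    shape = (1, -1, 1, 1) if xt.data.ndim == 4 else (1, -1)
    if training:
        mean = xt.data.mean(axis=axes)
        var = xt.data.var(axis=axes)
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xt.data - mean.reshape(shape)) * invstd.reshape(shape)
    out = gamma.data.reshape(shape) * xhat + beta.data.reshape(shape)
    n = xt.data.size // xt.data.shape[1]

    def back(g):
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes))
        if xt.requires_grad:
            gy = g * gamma.data.reshape(shape)
            if training:
                gsum = gy.sum(axis=axes, keepdims=True)
                gxsum = (gy * xhat).sum(axis=axes, keepdims=True)
                gx = (gy - gsum / n - xhat * gxsum / n) * invstd.reshape(shape)
            else:
                gx = gy * invstd.reshape(shape)
            xt._accum(gx)

    return Tensor._op(out, (xt, gamma, beta), back)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Layer normalisation over the last axis."""
    xt = Tensor._wrap(x)
    _report("layer_norm", 0)
    mean = xt.data.mean(axis=-1, keepdims=True)
    var = xt.data.var(axis=-1, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xt.data - mean) * invstd
    out = gamma.data * xhat + beta.data
    d = xt.data.shape[-1]

    def back(g):
        red = tuple(range(g.ndim - 1))
        if beta.requires_grad:
            beta._accum(g.sum(axis=red))
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=red))
        if xt.requires_grad:
            gy = g * gamma.data
            gsum = gy.sum(axis=-1, keepdims=True)
            gxsum = (gy * xhat).sum(axis=-1, keepdims=True)
            xt._accum((gy - gsum / d - xhat * gxsum / d) * invstd)

    return Tensor._op(out, (xt, gamma, beta), back)
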