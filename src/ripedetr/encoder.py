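"""Intra-scale encoder over the deepest pyramid level (AIFI), switchable
between standard multi-head self-attention and deformable attention.

The deformable variant (AIFI-DAT) keeps queries at every S5 position but
samples keys/values at learned offsets from a uniform reference grid:

  * a lightweight offset network (depthwise conv -> nonlinearity -> 1x1
    projection) predicts per-reference-point displacements from the query
    map;
  * features are gathered at the displaced points by exact bilinear
    interpolation;
  * attention logits receive a relative-position bias, bilinearly
    interpolated from a learned table at the continuous query-key
    displacements.

Reference points sit at cell centres, normalised to [-1, 1]; out-of-range
sample points are clamped to the feature-map border.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn.core import Tensor

__all__ = [
    "DATConfig",
    "reference_grid",
    "bilinear_sample",
    "MultiHeadSelfAttention",
    "DeformableAttention",
    "deformable_attention",
    "AIFI",
    "aifi_forward",
    "sine_position_embedding",
]


@dataclass
class DATConfig:
    d_model: int = 256
    heads: int = 8
    grid_factor: int = 1          # keys/values per grid cell of this stride
    offset_kernel: int = 5
    offset_range: float = 2.0     # max displacement, in grid cells

    def __post_init__(self):
        if self.d_model % self.heads:
            raise ValueError("d_model must be divisible by the head count")


def reference_grid(H: int, W: int, grid_factor: int = 1) -> np.ndarray:
    """Uniform reference points at cell centres, normalised to [-1, 1].

    Returns an (HG, WG, 2) array in (x, y) order with HG = H // factor.
    With factor 1 the points coincide exactly with pixel centres under the
    edge-based normalisation used by the bilinear sampler.
    """
    if H < grid_factor or W < grid_factor:
        raise ValueError("grid_factor larger than the feature map")
    HG, WG = H // grid_factor, W // grid_factor
    ys = (2.0 * np.arange(HG) + 1.0) / HG - 1.0
    xs = (2.0 * np.arange(WG) + 1.0) / WG - 1.0
    gx, gy = np.meshgrid(xs, ys, indexing="xy")
    return np.stack([gx, gy], axis=-1)


def bilinear_sample(z, points):
    """Exact bilinear interpolation of ``z`` (H, W, C) at normalised
    ``points`` (P, 2); the interpolation kernel is g(a, b) = max(0, 1-|a-b|)
    in pixel units, with border clamping."""
    zt = z if isinstance(z, Tensor) else Tensor(np.asarray(z))
    pt = points if isinstance(points, Tensor) else Tensor(np.asarray(points))
    H, W, C = zt.shape
    zmap = zt.transpose(2, 0, 1).reshape(1, C, H, W)
    out = nn.grid_sample(zmap, pt.reshape(1, -1, 2))  # (1, C, P)
    res = out.reshape(C, -1).transpose(1, 0)
    return res if isinstance(z, Tensor) or isinstance(points, Tensor) else res.data


def sine_position_embedding(H: int, W: int, d_model: int,
                            temperature: float = 10000.0) -> np.ndarray:
    """2-D sinusoidal position embedding, (H*W, d_model)."""
    if d_model % 4:
        raise ValueError("d_model must be divisible by 4")
    gw, gh = np.meshgrid(np.arange(W, dtype=np.float64),
                         np.arange(H, dtype=np.float64), indexing="xy")
    pos_dim = d_model // 4
    omega = 1.0 / temperature ** (np.arange(pos_dim) / pos_dim)
    out_w = gw.reshape(-1, 1) * omega
    out_h = gh.reshape(-1, 1) * omega
    emb = np.concatenate([np.sin(out_w), np.cos(out_w),
                          np.sin(out_h), np.cos(out_h)], axis=1)
    return emb.astype(np.float32)


class MultiHeadSelfAttention(nn.Module):
    def __init__(self, d_model: int, heads: int):
        super().__init__()
        if d_model % heads:
            raise ValueError("d_model must be divisible by heads")
        self.d_model, self.heads = d_model, heads
        self.wq = nn.Linear(d_model, d_model)
        self.wk = nn.Linear(d_model, d_model)
        self.wv = nn.Linear(d_model, d_model)
        self.wo = nn.Linear(d_model, d_model)

    def forward(self, x: Tensor, hw=None) -> Tensor:
        N, L, D = x.shape
        M, d = self.heads, self.d_model // self.heads
        q = self.wq(x).reshape(N, L, M, d).transpose(0, 2, 1, 3)
        k = self.wk(x).reshape(N, L, M, d).transpose(0, 2, 1, 3)
        v = self.wv(x).reshape(N, L, M, d).transpose(0, 2, 1, 3)
        attn = nn.softmax((q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d)), axis=-1)
        z = (attn @ v).transpose(0, 2, 1, 3).reshape(N, L, D)
        return self.wo(z)


class DeformableAttention(nn.Module):
    """Single-scale deformable attention with relative-position bias."""

    def __init__(self, cfg: DATConfig):
        super().__init__()
        self.cfg = cfg
        D = cfg.d_model
        self.wq = nn.Linear(D, D)
        self.wk = nn.Linear(D, D)
        self.wv = nn.Linear(D, D)
        self.wo = nn.Linear(D, D)
        self.offset_dw = nn.DepthwiseConv2d(D, cfg.offset_kernel)
        self.offset_proj = nn.Conv2d(D, 2, 1, bias=True)
        # table side spans displacements of +/- one full map
        self.bias_side = 31
        self.bias_table = nn.Parameter(
            np.zeros((cfg.heads, self.bias_side, self.bias_side), dtype=np.float32))

    # -- pieces -------------------------------------------------------------
    def offsets(self, q: Tensor, H: int, W: int) -> Tensor:
        """Predicted displacements (N, HG*WG, 2) in normalised units."""
        cfg = self.cfg
        N = q.shape[0]
        qmap = q.transpose(0, 2, 1).reshape(N, cfg.d_model, H, W)
        if cfg.grid_factor > 1:
            qmap = nn.avgpool2d(qmap, cfg.grid_factor, cfg.grid_factor)
        HG, WG = H // cfg.grid_factor, W // cfg.grid_factor
        o = self.offset_proj(self.offset_dw(qmap).silu())  # (N, 2, HG, WG)
        if np.any(~np.isfinite(o.data)):
            raise FloatingPointError("non-finite deformable-attention offsets")
        o = o.reshape(N, 2, HG * WG).transpose(0, 2, 1)
        # tanh-bounded, at most offset_range grid cells per axis
        scale = np.array([2.0 * cfg.offset_range / WG,
                          2.0 * cfg.offset_range / HG], dtype=np.float32)
        t = o * 2.0
        bounded = t.sigmoid() * 2.0 - 1.0  # tanh(o)
        return bounded * scale

    def _bias(self, points: Tensor, H: int, W: int, HG: int, WG: int) -> Tensor:
        """Relative-position bias (N, M, HW, P) interpolated from the table
        at continuous query-key displacements."""
        N, P, _ = points.shape
        qref = reference_grid(H, W, 1).reshape(-1, 2)  # (HW, 2) normalised
        # displacement in normalised units, range (-2, 2) -> table coords
        disp_x = points.reshape(N, 1, P, 2)[..., 0] - qref[None, :, None, 0]
        disp_y = points.reshape(N, 1, P, 2)[..., 1] - qref[None, :, None, 1]
        gx = (disp_x * 0.5).reshape(N, -1)
        gy = (disp_y * 0.5).reshape(N, -1)
        grid = nn.stack([gx, gy], axis=-1)  # (N, HW*P, 2)
        table = self.bias_table.reshape(1, self.cfg.heads, self.bias_side, self.bias_side)
        M = self.cfg.heads
        biases = []
        for n in range(N):
            b = nn.grid_sample(table, grid[n].reshape(1, -1, 2))  # (1, M, HW*P)
            biases.append(b)
        out = nn.concat(biases, axis=0)  # (N, M, HW*P)
        return out.reshape(N, M, -1, P)

    def forward(self, x: Tensor, hw) -> Tensor:
        """x: (N, H*W, d_model) token sequence; hw: (H, W)."""
        cfg = self.cfg
        H, W = hw
        N, L, D = x.shape
        M, d = cfg.heads, D // cfg.heads
        q = self.wq(x)
        dp = self.offsets(q, H, W)                     # (N, P, 2)
        ref = reference_grid(H, W, cfg.grid_factor).reshape(-1, 2)
        points = dp + ref[None].astype(np.float32)
        xmap = x.transpose(0, 2, 1).reshape(N, D, H, W)
        sampled = nn.grid_sample(xmap, points).transpose(0, 2, 1)  # (N, P, D)
        k = self.wk(sampled)
        v = self.wv(sampled)
        P = points.shape[1]
        qh = q.reshape(N, L, M, d).transpose(0, 2, 1, 3)
        kh = k.reshape(N, P, M, d).transpose(0, 2, 1, 3)
        vh = v.reshape(N, P, M, d).transpose(0, 2, 1, 3)
        logits = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        logits = logits + self._bias(points, H, W, H // cfg.grid_factor,
                                     W // cfg.grid_factor)
        attn = nn.softmax(logits, axis=-1)
        z = (attn @ vh).transpose(0, 2, 1, 3).reshape(N, L, D)
        return self.wo(z)


def deformable_attention(x, cfg: DATConfig, module: DeformableAttention = None):
    """Functional single-image deformable attention; ``x`` is (H, W, C)."""
    xt = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
    H, W, C = xt.shape
    mod = module if module is not None else DeformableAttention(cfg)
    out = mod(xt.reshape(1, H * W, C), (H, W))
    return out.reshape(H, W, C)


class EncoderLayer(nn.Module):
    """Post-norm transformer encoder layer with a pluggable attention."""

    def __init__(self, attn: nn.Module, d_model: int, ffn_dim: int):
        super().__init__()
        self.attn = attn
        self.norm1 = nn.LayerNorm(d_model)
        self.lin1 = nn.Linear(d_model, ffn_dim)
        self.lin2 = nn.Linear(ffn_dim, d_model)
        self.norm2 = nn.LayerNorm(d_model)

    def forward(self, x: Tensor, hw) -> Tensor:
        y = self.norm1(x + self.attn(x, hw))
        z = self.lin2(self.lin1(y).relu())
        return self.norm2(y + z)


class AIFI(nn.Module):
    """Attention-based intra-scale feature interaction over S5.

    ``mode='mhsa'`` is the baseline single encoder layer; ``mode='dat'``
    swaps in deformable attention.  A 2-D sinusoidal position embedding is
    added to the token sequence before attention in both modes.
    """

    def __init__(self, d_model: int = 256, heads: int = 8, ffn_dim: int = 1024,
                 mode: str = "mhsa", offset_kernel: int = 5, offset_range: float = 2.0,
                 grid_factor: int = 1):
        super().__init__()
        if mode not in ("mhsa", "dat"):
            raise ValueError(f"unknown AIFI mode {mode!r}")
        self.mode = mode
        self.d_model = d_model
        if mode == "dat":
            attn = DeformableAttention(DATConfig(
                d_model=d_model, heads=heads, offset_kernel=offset_kernel,
                offset_range=offset_range, grid_factor=grid_factor))
        else:
            attn = MultiHeadSelfAttention(d_model, heads)
        self.layer = EncoderLayer(attn, d_model, ffn_dim)
        self._pos_cache: dict = {}

    def forward(self, s5: Tensor) -> Tensor:
        N, C, H, W = s5.shape
        x = s5.reshape(N, C, H * W).transpose(0, 2, 1)  # flatten
        key = (H, W)
        if key not in self._pos_cache:
            self._pos_cache[key] = sine_position_embedding(H, W, C)
        x = x + Tensor(self._pos_cache[key][None])
        y = self.layer(x, (H, W))
        return y.transpose(0, 2, 1).reshape(N, C, H, W)  # inverse of flatten


def aifi_forward(s5, mode: str = "mhsa", cfg: dict = None) -> Tensor:
    """Build-and-run helper matching the module surface."""
    cfg = cfg or {}
    layer = AIFI(mode=mode, **cfg)
    layer.eval()
    st = s5 if isinstance(s5, Tensor) else Tensor(np.asarray(s5, dtype=np.float32))
    with nn.no_grad():
        return layer(st)
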