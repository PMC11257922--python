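"""Deformable-attention equations checked against literal loop oracles,
plus the AIFI layer contracts."""

import numpy as np
import pytest

from ripedetr import nn
from ripedetr.encoder import (AIFI, DATConfig, DeformableAttention,
                              MultiHeadSelfAttention, bilinear_sample,
                              reference_grid, deformable_attention)
from ripedetr.nn.core import Tensor


# ---------------------------------------------------------------------------
# reference grid and bilinear sampling
# ---------------------------------------------------------------------------

def test_reference_grid_smallest_case():
    g = reference_grid(2, 2, 1)
    assert g.shape == (2, 2, 2)
    assert np.allclose(sorted(np.unique(g[..., 0])), [-0.5, 0.5])
    assert np.allclose(sorted(np.unique(g[..., 1])), [-0.5, 0.5])


def test_reference_grid_downsampled():
    g = reference_grid(4, 4, 2)
    assert g.shape == (2, 2, 2)
    g8 = reference_grid(8, 8, 2)
    assert g8.shape == (4, 4, 2)
    # uniform spacing, symmetric about zero
    xs = g8[0, :, 0]
    assert np.allclose(np.diff(xs), xs[1] - xs[0])
    assert np.allclose(xs, -xs[::-1])


def test_bilinear_sample_identity_at_grid_points(rng):
    z = rng.standard_normal((5, 6, 3))
    pts = reference_grid(5, 6, 1).reshape(-1, 2)
    out = bilinear_sample(z, pts)
    assert np.allclose(out.reshape(5, 6, 3), z, atol=1e-12)


def test_bilinear_sample_midpoint_is_mean(rng):
    z = rng.standard_normal((4, 4, 2))
    H = W = 4
    p0 = np.array([(2 * 1 + 1) / W - 1, (2 * 2 + 1) / H - 1])
    p1 = np.array([(2 * 2 + 1) / W - 1, (2 * 2 + 1) / H - 1])
    mid = (p0 + p1) / 2
    out = bilinear_sample(z, mid[None])
    assert np.allclose(out[0], (z[2, 1] + z[2, 2]) / 2, atol=1e-12)


def _naive_bilinear(z, points):
    """Literal sum over all grid cells with kernel g(a,b)=max(0,1-|a-b|)."""
    H, W, C = z.shape
    out = np.zeros((len(points), C))
    for i, (gx, gy) in enumerate(points):
        px = (gx + 1) * 0.5 * W - 0.5
        py = (gy + 1) * 0.5 * H - 0.5
        px = min(max(px, 0.0), W - 1)
        py = min(max(py, 0.0), H - 1)
        for ry in range(H):
            for rx in range(W):
                g = max(0.0, 1 - abs(px - rx)) * max(0.0, 1 - abs(py - ry))
                out[i] += g * z[ry, rx]
    return out


def test_bilinear_sample_matches_naive_loop(rng):
    z = rng.standard_normal((5, 7, 3))
    pts = rng.uniform(-1.1, 1.1, (40, 2))  # includes out-of-range points
    assert np.allclose(bilinear_sample(z, pts), _naive_bilinear(z, pts), atol=1e-10)


# ---------------------------------------------------------------------------
# deformable attention vs a literal loop implementation
# ---------------------------------------------------------------------------

def _loop_deformable(x, mod: DeformableAttention, H, W):
    """Independent re-computation of the deformable-attention pipeline with
    explicit python loops: q = x Wq; offsets from the depthwise->silu->1x1
    network; bilinear sampling of keys/values at grid+offset; per-head
    softmax(q k^T / sqrt(d) + interpolated bias) v; concat; Wo."""
    cfg = mod.cfg
    D, M = cfg.d_model, cfg.heads
    d = D // M
    L = H * W

    def lin(v, layer):
        return v @ layer.weight.data + layer.bias.data

    q = lin(x, mod.wq)                                     # (L, D)

    # offset network on the q map
    qmap = q.reshape(H, W, D)
    k = cfg.offset_kernel
    pad = k // 2
    padded = np.zeros((H + 2 * pad, W + 2 * pad, D))
    padded[pad:pad + H, pad:pad + W] = qmap
    dw = np.zeros((H, W, D))
    for y in range(H):
        for xx in range(W):
            for ky in range(k):
                for kx in range(k):
                    dw[y, xx] += mod.offset_dw.weight.data[:, ky, kx] * \
                        padded[y + ky, xx + kx]
    s = 1 / (1 + np.exp(-dw))
    act = dw * s                                           # silu
    offs = np.zeros((H, W, 2))
    for y in range(H):
        for xx in range(W):
            offs[y, xx] = (mod.offset_proj.weight.data[:, :, 0, 0] @ act[y, xx]
                           + mod.offset_proj.bias.data)
    scale = np.array([2.0 * cfg.offset_range / W, 2.0 * cfg.offset_range / H])
    offs = np.tanh(offs) * scale

    ref = reference_grid(H, W, 1)
    pts = (ref + offs).reshape(-1, 2)
    sampled = _naive_bilinear(x.reshape(H, W, D), pts)     # (P, D)
    kmat = lin(sampled, mod.wk)
    vmat = lin(sampled, mod.wv)

    # relative position bias interpolated from the table
    side = mod.bias_side
    qref = reference_grid(H, W, 1).reshape(-1, 2)
    table = mod.bias_table.data                            # (M, side, side)
    bias = np.zeros((M, L, len(pts)))
    for m in range(M):
        for qi in range(L):
            for pj in range(len(pts)):
                gx = (pts[pj, 0] - qref[qi, 0]) * 0.5
                gy = (pts[pj, 1] - qref[qi, 1]) * 0.5
                bias[m, qi, pj] = _naive_bilinear(
                    table[m][:, :, None], np.array([[gx, gy]]))[0, 0]

    out = np.zeros((L, D))
    for m in range(M):
        qm = q[:, m * d:(m + 1) * d]
        km = kmat[:, m * d:(m + 1) * d]
        vm = vmat[:, m * d:(m + 1) * d]
        logits = qm @ km.T / np.sqrt(d) + bias[m]
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        attn = e / e.sum(axis=1, keepdims=True)
        out[:, m * d:(m + 1) * d] = attn @ vm
    return lin(out, mod.wo)


def test_deformable_attention_matches_loop_oracle(rng):
    H = W = 4
    cfg = DATConfig(d_model=8, heads=2, offset_kernel=3, offset_range=2.0)
    nn.seed_all(11)
    mod = DeformableAttention(cfg)
    # non-trivial offsets and bias
    mod.offset_proj.bias.data = rng.standard_normal(2).astype(np.float32) * 0.5
    mod.bias_table.data = rng.standard_normal(mod.bias_table.shape).astype(np.float32)
    x = rng.standard_normal((H * W, 8)).astype(np.float64)
    with nn.no_grad():
        mine = mod(Tensor(x[None]), (H, W)).data[0]
    ref = _loop_deformable(x, mod, H, W)
    assert np.abs(mine - ref).max() < 1e-4


def test_zero_offsets_reduce_to_attention_over_grid_samples(rng):
    """Offset net forced to zero + zero bias = standard attention between
    the tokens and the grid-sampled tokens."""
    H = W = 4
    cfg = DATConfig(d_model=8, heads=2, grid_factor=2)
    nn.seed_all(5)
    mod = DeformableAttention(cfg)
    mod.offset_dw.weight.data[:] = 0
    mod.offset_proj.weight.data[:] = 0
    mod.offset_proj.bias.data[:] = 0
    mod.bias_table.data[:] = 0
    x = rng.standard_normal((H * W, 8)).astype(np.float64)
    with nn.no_grad():
        mine = mod(Tensor(x[None]), (H, W)).data[0]

    # oracle: plain multi-head cross attention onto bilinear grid samples
    grid = reference_grid(H, W, 2).reshape(-1, 2)
    sampled = _naive_bilinear(x.reshape(H, W, 8), grid)
    q = x @ mod.wq.weight.data + mod.wq.bias.data
    k = sampled @ mod.wk.weight.data + mod.wk.bias.data
    v = sampled @ mod.wv.weight.data + mod.wv.bias.data
    d = 4
    out = np.zeros((H * W, 8))
    for m in range(2):
        qm, km, vm = (a[:, m * d:(m + 1) * d] for a in (q, k, v))
        logits = qm @ km.T / np.sqrt(d)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        out[:, m * d:(m + 1) * d] = (e / e.sum(axis=1, keepdims=True)) @ vm
    ref = out @ mod.wo.weight.data + mod.wo.bias.data
    assert np.abs(mine - ref).max() < 1e-5


def test_single_token_map_ignores_query_key_weights(rng):
    """With one key the softmax is identically 1, so the output is just
    Wo(Wv(sample)) + biases regardless of Wq, Wk."""
    cfg = DATConfig(d_model=8, heads=2, offset_kernel=1)
    nn.seed_all(9)
    mod = DeformableAttention(cfg)
    x = rng.standard_normal((1, 8)).astype(np.float64)
    with nn.no_grad():
        out1 = mod(Tensor(x[None]), (1, 1)).data
        mod.wq.weight.data = rng.standard_normal(mod.wq.weight.shape).astype(np.float32)
        mod.wk.weight.data = rng.standard_normal(mod.wk.weight.shape).astype(np.float32)
        out2 = mod(Tensor(x[None]), (1, 1)).data
    assert np.allclose(out1, out2, atol=1e-5)
    v = x @ mod.wv.weight.data + mod.wv.bias.data
    ref = v @ mod.wo.weight.data + mod.wo.bias.data
    assert np.abs(out1[0] - ref).max() < 1e-5


def test_offset_nan_fails_fast(rng):
    cfg = DATConfig(d_model=8, heads=2)
    nn.seed_all(1)
    mod = DeformableAttention(cfg)
    mod.offset_proj.bias.data[:] = np.nan
    with pytest.raises(FloatingPointError):
        with nn.no_grad():
            mod(Tensor(rng.standard_normal((1, 16, 8)).astype(np.float32)), (4, 4))


# ---------------------------------------------------------------------------
# AIFI layer
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("mode", ["mhsa", "dat"])
def test_aifi_preserves_s5_shape(mode, rng):
    nn.seed_all(2)
    layer = AIFI(d_model=16, heads=4, ffn_dim=32, mode=mode)
    layer.eval()
    s5 = Tensor(rng.standard_normal((2, 16, 5, 5)).astype(np.float32))
    with nn.no_grad():
        out = layer(s5)
    assert out.shape == s5.shape


def test_flatten_reshape_inverse(rng):
    x = rng.standard_normal((2, 8, 4, 6))
    t = Tensor(x)
    flat = t.reshape(2, 8, 24).transpose(0, 2, 1)
    back = flat.transpose(0, 2, 1).reshape(2, 8, 4, 6)
    assert np.array_equal(back.data, x)


def test_attention_rows_sum_to_one(rng):
    from ripedetr.nn.core import softmax
    logits = Tensor(rng.standard_normal((2, 3, 5, 7)))
    s = softmax(logits, axis=-1)
    assert np.allclose(s.data.sum(axis=-1), 1.0, atol=1e-6)


def test_mhsa_token_mixing_is_permutation_equivariant(rng):
    nn.seed_all(4)
    attn = MultiHeadSelfAttention(8, 2)
    x = rng.standard_normal((1, 6, 8)).astype(np.float64)
    perm = np.random.default_rng(0).permutation(6)
    with nn.no_grad():
        out = attn(Tensor(x)).data
        out_p = attn(Tensor(x[:, perm])).data
    assert np.allclose(out[:, perm], out_p, atol=1e-8)


def test_functional_wrapper_shape():
    out = deformable_attention(np.zeros((4, 4, 8), np.float32),
                               DATConfig(d_model=8, heads=2))
    assert out.shape == (4, 4, 8)
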