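"""RT-DETR-style decoding stack.

End-to-end set prediction without non-maximum suppression: encoder tokens
from the fused pyramid are scored, the top-K become initial object queries
with their predicted boxes as references (IoU-aware query selection), a
stack of decoder layers iteratively refines the references in sigmoid
space, and one-to-one bipartite (Hungarian) matching assigns predictions
to ground truth for the loss.  During training, denoising query groups --
jittered copies of the ground-truth boxes plus label-flipped negatives --
are decoded alongside the matching queries behind an attention mask that
blocks any information flow between groups or into the matching queries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from . import nn
from .nn.core import Tensor
from . import box_losses

__all__ = [
    "HeadConfig",
    "LossConfig",
    "QuerySet",
    "DetectionSet",
    "MatchResult",
    "hungarian_match",
    "topk_queries",
    "denoising_queries",
    "MSDeformAttn",
    "RTDETRHead",
    "total_loss",
]


# ---------------------------------------------------------------------------
# configs and containers
# ---------------------------------------------------------------------------

@dataclass
class HeadConfig:
    d_model: int = 256
    n_queries: int = 300
    depth: int = 3
    heads: int = 8
    ffn_dim: int = 1024
    n_points: int = 4
    n_levels: int = 3
    num_classes: int = 5
    dn_queries: int = 100       # approximate total denoising queries
    dn_noise: float = 0.5


@dataclass
class LossConfig:
    box: str = "giou"                   # giou | eiou | inner_eiou
    inner_ratio: float = box_losses.DEFAULT_INNER_RATIO
    class_weight: float = 1.0
    l1_weight: float = 5.0
    iou_weight: float = 2.0
    # matching cost weights (class / L1 / GIoU)
    cost_class: float = 2.0
    cost_l1: float = 5.0
    cost_iou: float = 2.0

    def __post_init__(self):
        if self.box not in ("giou", "eiou", "inner_eiou"):
            raise ValueError(f"unknown box loss {self.box!r}")


@dataclass
class QuerySet:
    """Decoder input: content embeddings plus reference boxes (normalised
    cxcywh), with the first ``dn_count`` entries being denoising queries."""

    embeddings: Tensor            # (N, nq_total, D)
    ref_boxes: Tensor             # (N, nq_total, 4) in [0, 1]
    dn_count: int = 0
    attn_mask: Optional[np.ndarray] = None   # True = blocked
    dn_meta: Optional[dict] = None


@dataclass
class DetectionSet:
    """Scored, classed boxes for one image, confidence-sorted descending,
    boxes clipped to the image."""

    boxes: np.ndarray             # (K, 4) pixel xyxy
    classes: np.ndarray           # (K,)
    scores: np.ndarray            # (K,) in [0, 1]


@dataclass
class MatchResult:
    pairs: List[tuple]            # (query index, ground-truth index)
    unmatched_queries: List[int]  # assigned background
    total_cost: float


# ---------------------------------------------------------------------------
# free operations
# ---------------------------------------------------------------------------

def hungarian_match(cost: np.ndarray) -> MatchResult:
    """Minimal-total-cost one-to-one assignment of queries to ground truth."""
    cost = np.asarray(cost, dtype=np.float64)
    if cost.ndim != 2:
        raise ValueError("cost must be 2-D")
    if np.any(np.isnan(cost)):
        raise FloatingPointError("NaN in matching cost")
    nq, ng = cost.shape
    if ng == 0:
        return MatchResult([], list(range(nq)), 0.0)
    rows, cols = linear_sum_assignment(cost)
    pairs = sorted(zip(rows.tolist(), cols.tolist()))
    matched = {q for q, _ in pairs}
    unmatched = [q for q in range(nq) if q not in matched]
    return MatchResult(pairs, unmatched, float(cost[rows, cols].sum()))


def topk_queries(scores: np.ndarray, k: int) -> np.ndarray:
    """Indices of the K best selection scores, ties broken by lower index
    (stable), so the selected *set* is independent of evaluation order."""
    scores = np.asarray(scores)
    if k > scores.shape[-1]:
        raise ValueError(f"K={k} exceeds token count {scores.shape[-1]}")
    order = np.argsort(-scores, axis=-1, kind="stable")
    return order[..., :k]


def denoising_queries(gt_boxes: np.ndarray, gt_classes: np.ndarray,
                      n_groups: int, noise_scale: float,
                      num_classes: int, rng: np.random.Generator):
    """Build denoising-query targets for one image.

    Returns (boxes (G*2*n, 4) cxcywh, labels (G*2*n,), positive mask) where
    each group holds ``n`` jittered positives (centre shifted by at most
    ``noise_scale/2`` of the box size, size scaled within ``1 +/-
    noise_scale/2``) followed by ``n`` label-flipped negatives with larger
    jitter.  ``noise_scale = 0`` reproduces the ground truth exactly.
    """
    gt_boxes = np.asarray(gt_boxes, dtype=np.float64)   # cxcywh normalised
    gt_classes = np.asarray(gt_classes, dtype=np.intp)
    n = len(gt_boxes)
    if n == 0:
        raise ValueError("denoising requires at least one ground-truth box")
    boxes, labels, positive = [], [], []
    for _ in range(n_groups):
        # positives
        shift = (rng.uniform(-0.5, 0.5, (n, 2)) * noise_scale) * gt_boxes[:, 2:]
        scale = 1.0 + rng.uniform(-0.5, 0.5, (n, 2)) * noise_scale
        pos = gt_boxes.copy()
        pos[:, :2] += shift
        pos[:, 2:] *= scale
        boxes.append(pos)
        labels.append(gt_classes.copy())
        positive.append(np.ones(n, dtype=bool))
        # negatives: larger jitter, wrong labels
        shift = (rng.uniform(0.5, 1.0, (n, 2)) * rng.choice([-1, 1], (n, 2))
                 * noise_scale) * gt_boxes[:, 2:]
        scale = 1.0 + rng.uniform(0.5, 1.0, (n, 2)) * rng.choice([-1, 1], (n, 2)) * noise_scale
        neg = gt_boxes.copy()
        neg[:, :2] += shift
        neg[:, 2:] *= np.clip(scale, 0.05, None)
        boxes.append(neg)
        flip = (gt_classes + rng.integers(1, max(num_classes, 2), n)) % num_classes
        labels.append(flip)
        positive.append(np.zeros(n, dtype=bool))
    out_boxes = np.clip(np.concatenate(boxes), 1e-4, 1.0)
    return out_boxes, np.concatenate(labels), np.concatenate(positive)


def dn_attention_mask(dn_count: int, group_size: int, n_match: int) -> np.ndarray:
    """Additive-mask pattern (True = blocked) for denoising decoding.

    Blocks attention between different denoising groups, from denoising
    queries to matching queries, and from matching queries into any
    denoising group.
    """
    total = dn_count + n_match
    mask = np.zeros((total, total), dtype=bool)
    if dn_count:
        mask[:dn_count, :] = True
        n_groups = dn_count // group_size
        for g in range(n_groups):
            lo, hi = g * group_size, (g + 1) * group_size
            mask[lo:hi, lo:hi] = False
        mask[dn_count:, :dn_count] = True
    return mask


def _inverse_sigmoid(x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    x = np.clip(x, eps, 1 - eps)
    return np.log(x / (1 - x))


def _box_cxcywh_to_xyxy_t(b: Tensor) -> Tensor:
    cx, cy, w, h = b[..., 0], b[..., 1], b[..., 2], b[..., 3]
    return nn.stack([cx - w * 0.5, cy - h * 0.5, cx + w * 0.5, cy + h * 0.5], axis=-1)


def _box_cxcywh_to_xyxy(b: np.ndarray) -> np.ndarray:
    out = np.empty_like(b)
    out[..., 0] = b[..., 0] - b[..., 2] * 0.5
    out[..., 1] = b[..., 1] - b[..., 3] * 0.5
    out[..., 2] = b[..., 0] + b[..., 2] * 0.5
    out[..., 3] = b[..., 1] + b[..., 3] * 0.5
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class MSDeformAttn(nn.Module):
    """Multi-scale deformable cross-attention: each query samples a few
    points per head and level around its reference box and mixes them with
    learned attention weights."""

    def __init__(self, d_model: int, heads: int, n_levels: int, n_points: int):
        super().__init__()
        self.d_model, self.heads = d_model, heads
        self.n_levels, self.n_points = n_levels, n_points
        self.sampling_offsets = nn.Linear(d_model, heads * n_levels * n_points * 2)
        self.attention_weights = nn.Linear(d_model, heads * n_levels * n_points)
        self.value_proj = nn.Linear(d_model, d_model)
        self.output_proj = nn.Linear(d_model, d_model)

    def forward(self, query: Tensor, ref_boxes: np.ndarray,
                value_levels: List[Tensor]) -> Tensor:
        """query (N, nq, D); ref_boxes (N, nq, 4) cxcywh in [0,1] (numpy,
        detached); value_levels: per-level (N, D, H, W) value maps."""
        N, nq, D = query.shape
        M, L, K = self.heads, self.n_levels, self.n_points
        d = D // M
        offs = self.sampling_offsets(query).reshape(N, nq, M, L, K, 2)
        w = self.attention_weights(query).reshape(N, nq, M, L * K)
        w = nn.softmax(w, axis=-1).reshape(N, nq, M, L, K)
        centers = ref_boxes[:, :, None, None, None, :2]
        sizes = ref_boxes[:, :, None, None, None, 2:]
        locs = Tensor(centers) + offs * Tensor(sizes) * (0.5 / K)
        per_head = []
        for lvl, vmap in enumerate(value_levels):
            _, _, H, W = vmap.shape
            vtok = vmap.reshape(N, D, H * W).transpose(0, 2, 1)
            vtok = self.value_proj(vtok)
            vh = (vtok.transpose(0, 2, 1).reshape(N, D, H, W)
                  .reshape(N, M, d, H, W).reshape(N * M, d, H, W))
            pts = locs[:, :, :, lvl].transpose(0, 2, 1, 3, 4)  # N,M,nq,K,2
            pts = (pts * 2.0 - 1.0).reshape(N * M, nq * K, 2)
            samp = nn.grid_sample(vh, pts)                     # (N*M, d, nq*K)
            samp = samp.reshape(N, M, d, nq, K)
            wl = w[:, :, :, lvl].transpose(0, 2, 1, 3).reshape(N, M, 1, nq, K)
            per_head.append((samp * wl).sum(axis=-1))          # (N, M, d, nq)
        agg = per_head[0]
        for p in per_head[1:]:
            agg = agg + p
        out = agg.transpose(0, 3, 1, 2).reshape(N, nq, D)
        return self.output_proj(out)


class MaskedSelfAttention(nn.Module):
    def __init__(self, d_model: int, heads: int):
        super().__init__()
        self.heads = heads
        self.wq = nn.Linear(d_model, d_model)
        self.wk = nn.Linear(d_model, d_model)
        self.wv = nn.Linear(d_model, d_model)
        self.wo = nn.Linear(d_model, d_model)

    def forward(self, x: Tensor, pos: Tensor,
                mask: Optional[np.ndarray] = None) -> Tensor:
        N, L, D = x.shape
        M = self.heads
        d = D // M
        xq = x + pos
        q = self.wq(xq).reshape(N, L, M, d).transpose(0, 2, 1, 3)
        k = self.wk(xq).reshape(N, L, M, d).transpose(0, 2, 1, 3)
        v = self.wv(x).reshape(N, L, M, d).transpose(0, 2, 1, 3)
        logits = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(d))
        if mask is not None:
            add = np.where(mask, -1e9, 0.0).astype(np.float32)
            logits = logits + Tensor(add[None, None])
        attn = nn.softmax(logits, axis=-1)
        z = (attn @ v).transpose(0, 2, 1, 3).reshape(N, L, D)
        return self.wo(z)


class DecoderLayer(nn.Module):
    def __init__(self, cfg: HeadConfig):
        super().__init__()
        D = cfg.d_model
        self.self_attn = MaskedSelfAttention(D, cfg.heads)
        self.norm1 = nn.LayerNorm(D)
        self.cross_attn = MSDeformAttn(D, cfg.heads, cfg.n_levels, cfg.n_points)
        self.norm2 = nn.LayerNorm(D)
        self.lin1 = nn.Linear(D, cfg.ffn_dim)
        self.lin2 = nn.Linear(cfg.ffn_dim, D)
        self.norm3 = nn.LayerNorm(D)

    def forward(self, x: Tensor, pos: Tensor, refs: np.ndarray,
                value_levels, mask) -> Tensor:
        x = self.norm1(x + self.self_attn(x, pos, mask))
        x = self.norm2(x + self.cross_attn(x + pos, refs, value_levels))
        return self.norm3(x + self.lin2(self.lin1(x).relu()))


class RTDETRHead(nn.Module):
    """Query selection + denoising + iterative decoder + prediction heads."""

    def __init__(self, cfg: Optional[HeadConfig] = None):
        super().__init__()
        cfg = cfg or HeadConfig()
        self.cfg = cfg
        D = cfg.d_model
        self.enc_output = nn.Linear(D, D)
        self.enc_norm = nn.LayerNorm(D)
        self.enc_score_head = nn.Linear(D, cfg.num_classes)
        self.enc_bbox_head = nn.MLP([D, D, D, 4])
        self.denoise_class_embed = nn.Embedding(cfg.num_classes + 1, D)
        self.query_pos_head = nn.MLP([4, 2 * D, D])
        self.layers = nn.ModuleList([DecoderLayer(cfg) for _ in range(cfg.depth)])
        self.score_heads = nn.ModuleList(
            [nn.Linear(D, cfg.num_classes) for _ in range(cfg.depth)])
        self.bbox_heads = nn.ModuleList(
            [nn.MLP([D, D, D, 4]) for _ in range(cfg.depth)])
        self._anchor_cache: dict = {}

    # -- anchors ------------------------------------------------------------
    def _anchors(self, shapes) -> np.ndarray:
        key = tuple(shapes)
        if key not in self._anchor_cache:
            all_a = []
            for lvl, (H, W) in enumerate(shapes):
                gy, gx = np.meshgrid(np.arange(H), np.arange(W), indexing="ij")
                cx = (gx.reshape(-1) + 0.5) / W
                cy = (gy.reshape(-1) + 0.5) / H
                wh = np.full(H * W, 0.05 * 2 ** lvl)
                all_a.append(np.stack([cx, cy, wh, wh], axis=1))
            self._anchor_cache[key] = np.concatenate(all_a).astype(np.float32)
        return self._anchor_cache[key]

    # -- query selection ----------------------------------------------------
    def select_queries(self, memory: Tensor, shapes, k: int):
        """IoU-aware selection: score all tokens, keep the top-K, and turn
        their predicted boxes into initial references."""
        N, L, D = memory.shape
        if k > L:
            raise ValueError(f"K={k} exceeds token count {L}")
        feat = self.enc_norm(self.enc_output(memory))
        logits = self.enc_score_head(feat)                 # (N, L, nc)
        sel_score = logits.data.max(axis=-1)
        idx = topk_queries(sel_score, k)                   # (N, k)
        rows = np.arange(N)[:, None]
        feat_sel = feat[rows, idx]                         # (N, k, D)
        logits_sel = logits[rows, idx]
        anchors = self._anchors(shapes)[idx]               # (N, k, 4)
        deltas = self.enc_bbox_head(feat_sel)
        boxes = (deltas + Tensor(_inverse_sigmoid(anchors))).sigmoid()
        return feat_sel, logits_sel, boxes, idx

    # -- decoding -----------------------------------------------------------
    def forward(self, pyramid: Sequence[Tensor], targets=None,
                rng: Optional[np.random.Generator] = None):
        cfg = self.cfg
        N = pyramid[0].shape[0]
        shapes = [(p.shape[2], p.shape[3]) for p in pyramid]
        tokens = [p.reshape(p.shape[0], p.shape[1], -1).transpose(0, 2, 1)
                  for p in pyramid]
        memory = nn.concat(tokens, axis=1)                 # (N, L, D)

        feat_sel, enc_logits, enc_boxes, _ = self.select_queries(
            memory, shapes, cfg.n_queries)

        dn_meta = None
        mask = None
        if targets is not None:
            rng = rng or np.random.default_rng(0)
            dn_embed, dn_boxes, dn_meta = self._build_denoising(targets, rng)
            n_dn = dn_boxes.shape[1]
            embed = nn.concat([dn_embed, feat_sel.detach()], axis=1)
            refs0 = np.concatenate([dn_boxes, enc_boxes.data], axis=1)
            mask = dn_attention_mask(n_dn, dn_meta["group_size"], cfg.n_queries)
        else:
            embed = feat_sel.detach()
            refs0 = enc_boxes.data.copy()
            n_dn = 0

        value_levels = [p for p in pyramid]
        x = embed
        refs = refs0.astype(np.float32)
        layer_logits, layer_boxes = [], []
        for layer, score_head, bbox_head in zip(self.layers, self.score_heads,
                                                self.bbox_heads):
            pos = self.query_pos_head(Tensor(refs))
            x = layer(x, pos, refs, value_levels, mask)
            delta = bbox_head(x)
            boxes = (delta + Tensor(_inverse_sigmoid(refs))).sigmoid()
            logits = score_head(x)
            layer_logits.append(logits)
            layer_boxes.append(boxes)
            refs = boxes.data.copy()                      # detached refinement

        if targets is None:
            return {"logits": layer_logits[-1], "boxes": layer_boxes[-1]}
        match_layers = [(lg[:, n_dn:], bx[:, n_dn:])
                        for lg, bx in zip(layer_logits, layer_boxes)]
        dn_layers = [(lg[:, :n_dn], bx[:, :n_dn])
                     for lg, bx in zip(layer_logits, layer_boxes)]
        return {
            "layers": match_layers,
            "dn_layers": dn_layers,
            "enc": (enc_logits, enc_boxes),
            "dn_count": n_dn,
            "dn_meta": dn_meta,
        }

    def _build_denoising(self, targets, rng):
        """Assemble the padded denoising fragment for a batch."""
        cfg = self.cfg
        max_gt = max(len(t["classes"]) for t in targets)
        max_gt = max(max_gt, 1)
        n_groups = max(1, cfg.dn_queries // (2 * max_gt))
        group_size = 2 * max_gt
        n_dn = n_groups * group_size
        N = len(targets)
        all_boxes = np.zeros((N, n_dn, 4), dtype=np.float32)
        all_labels = np.full((N, n_dn), cfg.num_classes, dtype=np.intp)
        pos_mask = np.zeros((N, n_dn), dtype=bool)
        gt_index = np.full((N, n_dn), -1, dtype=np.intp)
        for i, t in enumerate(targets):
            n = len(t["classes"])
            if n == 0:
                all_boxes[i, :, :] = 0.5
                continue
            boxes, labels, pos = denoising_queries(
                t["boxes"], t["classes"], n_groups, cfg.dn_noise,
                cfg.num_classes, rng)
            # scatter each group into its padded slot
            for g in range(n_groups):
                lo = g * group_size
                src = g * 2 * n
                all_boxes[i, lo:lo + n] = boxes[src:src + n]
                all_labels[i, lo:lo + n] = labels[src:src + n]
                pos_mask[i, lo:lo + n] = pos[src:src + n]
                gt_index[i, lo:lo + n] = np.arange(n)
                all_boxes[i, lo + max_gt:lo + max_gt + n] = boxes[src + n:src + 2 * n]
                all_labels[i, lo + max_gt:lo + max_gt + n] = labels[src + n:src + 2 * n]
                gt_index[i, lo + max_gt:lo + max_gt + n] = np.arange(n)
            # unused padding slots keep background label and centre boxes
            pad = all_boxes[i, :, 2] == 0
            all_boxes[i, pad] = np.array([0.5, 0.5, 0.1, 0.1])
        embed = self.denoise_class_embed(all_labels)
        meta = {"group_size": group_size, "n_groups": n_groups,
                "positive": pos_mask, "gt_index": gt_index,
                "labels": all_labels}
        return embed, all_boxes, meta

    # -- inference ----------------------------------------------------------
    def detections(self, outputs, image_size: int, top: int = 300) -> List[DetectionSet]:
        logits, boxes = outputs["logits"], outputs["boxes"]
        N, nq, nc = logits.shape
        results = []
        for i in range(N):
            scores = 1.0 / (1.0 + np.exp(-logits.data[i]))   # (nq, nc)
            flat = scores.reshape(-1)
            k = min(top, flat.size)
            idx = np.argsort(-flat, kind="stable")[:k]
            qi, ci = idx // nc, idx % nc
            b = _box_cxcywh_to_xyxy(boxes.data[i][qi]) * image_size
            b = np.clip(b, 0, image_size)
            results.append(DetectionSet(boxes=b, classes=ci.astype(int),
                                        scores=flat[idx]))
        return results


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _match_cost(logits: np.ndarray, boxes: np.ndarray, gt_boxes: np.ndarray,
                gt_classes: np.ndarray, cfg: LossConfig) -> np.ndarray:
    """Focal-style class cost + L1 + GIoU, (nq, ngt)."""
    p = 1.0 / (1.0 + np.exp(-logits))
    alpha, gamma = 0.25, 2.0
    pos = alpha * (1 - p) ** gamma * (-np.log(p + 1e-8))
    neg = (1 - alpha) * p ** gamma * (-np.log(1 - p + 1e-8))
    cost_class = pos[:, gt_classes] - neg[:, gt_classes]
    cost_l1 = np.abs(boxes[:, None, :] - gt_boxes[None, :, :]).sum(-1)
    a = _box_cxcywh_to_xyxy(boxes)
    b = _box_cxcywh_to_xyxy(gt_boxes)
    g = box_losses.giou(a[:, None, :].repeat(len(gt_boxes), 1), b[None, :, :].repeat(len(boxes), 0))
    return (cfg.cost_class * cost_class + cfg.cost_l1 * cost_l1
            + cfg.cost_iou * (1.0 - g))


def _box_loss_terms(pred_xyxy: Tensor, gt_xyxy: np.ndarray, cfg: LossConfig):
    gt = Tensor(gt_xyxy)
    if cfg.box == "giou":
        return (1.0 - box_losses.giou(pred_xyxy, gt)).sum()
    if cfg.box == "eiou":
        return box_losses.eiou(pred_xyxy, gt).sum()
    return box_losses.inner_eiou(pred_xyxy, gt, ratio=cfg.inner_ratio).sum()


def _classification_loss(logits: Tensor, target_q: np.ndarray,
                         alpha: float = 0.75, gamma: float = 2.0) -> Tensor:
    """IoU-weighted focal (varifocal-style) classification loss.

    ``target_q`` holds the IoU of the matched prediction on its class
    channel and zero elsewhere; negatives are down-weighted by p**gamma.
    """
    p = logits.sigmoid().clamp(1e-6, 1 - 1e-6)
    q = Tensor(target_q.astype(logits.dtype.type))
    weight = Tensor((target_q > 0).astype(logits.dtype.type)) * q \
        + alpha * (p.detach() ** gamma) * Tensor((target_q == 0).astype(logits.dtype.type))
    bce = -(q * p.log() + (1.0 - q) * (1.0 - p).log())
    return (weight * bce).sum()


def total_loss(outputs: dict, targets: Sequence[dict], cfg: Optional[LossConfig] = None):
    """Weighted sum of classification, L1 and IoU-family box losses over
    all decoder layers, the encoder-selection head and denoising groups.

    ``targets``: per image, dict with 'boxes' (n, 4) normalised cxcywh and
    'classes' (n,).  Returns (scalar Tensor, dict of component floats).
    """
    cfg = cfg or LossConfig()
    dn_count = outputs.get("dn_count", 0)
    comps = {"class": 0.0, "l1": 0.0, "box": 0.0}
    terms = []
    num_gt = sum(len(t["classes"]) for t in targets)
    norm = max(num_gt, 1)

    def add_supervised(logits: Tensor, boxes: Tensor, match_per_image):
        nonlocal comps
        N, nq, nc = logits.shape
        target_q = np.zeros((N, nq, nc), dtype=np.float64)
        sel_q, sel_gt_boxes = [], []
        for i, (t, pairs) in enumerate(zip(targets, match_per_image)):
            if not pairs:
                continue
            qidx = np.array([q for q, _ in pairs])
            gidx = np.array([g for _, g in pairs])
            pb = _box_cxcywh_to_xyxy(boxes.data[i][qidx])
            gb = _box_cxcywh_to_xyxy(np.asarray(t["boxes"])[gidx])
            ious = np.array([box_losses.iou(a, b) for a, b in zip(pb, gb)])
            target_q[i, qidx, np.asarray(t["classes"])[gidx]] = np.clip(ious, 0.01, 1)
            sel_q.append((i, qidx, gidx))
        cls = _classification_loss(logits, target_q) * (1.0 / norm)
        l1 = None
        boxl = None
        for i, qidx, gidx in sel_q:
            t = targets[i]
            pred = boxes[i][qidx]
            gt = np.asarray(t["boxes"])[gidx]
            d = (pred - Tensor(gt)).abs().sum()
            l1 = d if l1 is None else l1 + d
            bl = _box_loss_terms(_box_cxcywh_to_xyxy_t(pred), _box_cxcywh_to_xyxy(gt), cfg)
            boxl = bl if boxl is None else boxl + bl
        term = cfg.class_weight * cls
        comps["class"] += float(cls.data)
        if l1 is not None:
            l1 = l1 * (1.0 / norm)
            boxl = boxl * (1.0 / norm)
            term = term + cfg.l1_weight * l1 + cfg.iou_weight * boxl
            comps["l1"] += float(l1.data)
            comps["box"] += float(boxl.data)
        terms.append(term)

    # decoder layers + encoder head: Hungarian matching per image
    supervised = list(outputs["layers"]) + [outputs["enc"]]
    for logits, boxes in supervised:
        matches = []
        for i, t in enumerate(targets):
            gt_b = np.asarray(t["boxes"], dtype=np.float64)
            gt_c = np.asarray(t["classes"], dtype=np.intp)
            if len(gt_c) == 0:
                matches.append([])
                continue
            cost = _match_cost(logits.data[i], boxes.data[i], gt_b, gt_c, cfg)
            matches.append(hungarian_match(cost).pairs)
        add_supervised(logits, boxes, matches)

    # denoising part: assignment is known
    if dn_count and outputs.get("dn_meta") is not None:
        meta = outputs["dn_meta"]
        for logits_all, boxes_all in outputs["dn_layers"]:
            matches = []
            for i, t in enumerate(targets):
                pos = meta["positive"][i]
                gidx = meta["gt_index"][i]
                pairs = [(int(q), int(gidx[q])) for q in np.where(pos)[0]]
                matches.append(pairs)
            add_supervised(logits_all, boxes_all, matches)

    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out, comps
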