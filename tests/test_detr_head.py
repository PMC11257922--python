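"""Query selection, Hungarian matching, denoising and decoder contracts."""

import itertools

import numpy as np
import pytest

from ripedetr import nn
from ripedetr.detr_head import (HeadConfig, LossConfig, RTDETRHead,
                                denoising_queries, dn_attention_mask,
                                hungarian_match, topk_queries, total_loss)
from ripedetr.model import ModelConfig, build_model
from ripedetr.nn.core import Tensor


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

def test_topk_selects_dominant_token():
    scores = np.array([0.1, 0.2, 5.0, 0.3])
    assert topk_queries(scores, 1).tolist() == [2]


def test_topk_breaks_ties_by_index():
    scores = np.array([1.0, 3.0, 3.0, 3.0, 0.5])
    assert topk_queries(scores, 2).tolist() == [1, 2]


def test_topk_matches_exhaustive_sort_oracle(rng):
    for _ in range(20):
        scores = rng.standard_normal(30)
        k = int(rng.integers(1, 30))
        mine = set(topk_queries(scores, k).tolist())
        ref = set(sorted(range(30), key=lambda i: (-scores[i], i))[:k])
        assert mine == ref


def test_topk_rejects_oversized_k():
    with pytest.raises(ValueError):
        topk_queries(np.zeros(5), 6)


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_identity_dominant_cost_gives_identity_assignment():
    cost = np.full((3, 3), 10.0)
    np.fill_diagonal(cost, 0.0)
    res = hungarian_match(cost)
    assert res.pairs == [(0, 0), (1, 1), (2, 2)]
    assert res.total_cost == 0.0


def test_hungarian_matches_brute_force_enumeration(rng):
    """Optimality vs exhaustive enumeration for up to 5 ground truths."""
    for trial in range(30):
        nq = int(rng.integers(3, 8))
        ng = int(rng.integers(1, min(nq, 5) + 1))
        cost = rng.standard_normal((nq, ng))
        res = hungarian_match(cost)
        best = min(sum(cost[q, g] for g, q in enumerate(qs))
                   for qs in itertools.permutations(range(nq), ng))
        assert res.total_cost == pytest.approx(best, abs=1e-9)
        assert len(res.pairs) == ng
        assert len({q for q, _ in res.pairs}) == ng  # one-to-one


def test_empty_ground_truth_maps_everything_to_background():
    res = hungarian_match(np.zeros((4, 0)))
    assert res.pairs == []
    assert res.unmatched_queries == [0, 1, 2, 3]


def test_nan_cost_fails_fast():
    cost = np.zeros((2, 2))
    cost[0, 1] = np.nan
    with pytest.raises(FloatingPointError):
        hungarian_match(cost)


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

def test_zero_noise_reproduces_ground_truth():
    gt = np.array([[0.5, 0.5, 0.2, 0.3], [0.2, 0.8, 0.1, 0.1]])
    cls = np.array([1, 4])
    boxes, labels, pos = denoising_queries(gt, cls, n_groups=2, noise_scale=0.0,
                                           num_classes=5,
                                           rng=np.random.default_rng(0))
    assert boxes.shape == (8, 4)
    for g in range(2):
        assert np.allclose(boxes[g * 4:g * 4 + 2], gt)   # positives exact
        assert np.array_equal(labels[g * 4:g * 4 + 2], cls)
    # negatives carry flipped labels
    assert np.all(labels[~pos] != np.repeat(cls[None], 2, 0).reshape(-1)[[0, 1, 0, 1]])


def test_noise_is_bounded_by_scale():
    gt = np.array([[0.5, 0.5, 0.2, 0.2]])
    rng = np.random.default_rng(1)
    boxes, _, pos = denoising_queries(gt, np.array([0]), 50, 0.4, 5, rng)
    pos_boxes = boxes[pos]
    assert np.all(np.abs(pos_boxes[:, :2] - 0.5) <= 0.4 * 0.2 / 2 + 1e-9)
    assert np.all(np.abs(pos_boxes[:, 2:] / 0.2 - 1.0) <= 0.2 + 1e-9)


def test_group_count_scales_query_fragment_linearly():
    gt = np.array([[0.5, 0.5, 0.2, 0.2], [0.3, 0.3, 0.1, 0.1]])
    for g in (1, 2, 5):
        boxes, labels, _ = denoising_queries(gt, np.array([0, 1]), g, 0.3, 5,
                                             np.random.default_rng(0))
        assert len(boxes) == len(labels) == g * 2 * 2


def test_denoising_mask_blocks_leaks():
    mask = dn_attention_mask(dn_count=6, group_size=3, n_match=4)
    assert mask.shape == (10, 10)
    # denoise -> match blocked everywhere
    assert mask[:6, 6:].all()
    # match -> denoise blocked
    assert mask[6:, :6].all()
    # cross-group blocked, within-group open
    assert mask[0, 3] and mask[3, 0]
    assert not mask[0, 2] and not mask[4, 5]
    # matching queries attend freely among themselves
    assert not mask[6:, 6:].any()


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def _tiny_head_inputs(rng, cfg):
    D = cfg.d_model
    p3 = Tensor(rng.standard_normal((1, D, 8, 8)).astype(np.float32))
    p4 = Tensor(rng.standard_normal((1, D, 4, 4)).astype(np.float32))
    p5 = Tensor(rng.standard_normal((1, D, 2, 2)).astype(np.float32))
    return [p3, p4, p5]


def test_zero_decoder_weights_pass_references_through(rng):
    cfg = HeadConfig(d_model=16, n_queries=10, depth=2, heads=2, ffn_dim=16)
    nn.seed_all(0)
    head = RTDETRHead(cfg)
    head.eval()
    for name, p in head.named_parameters():
        if "bbox_heads" in name:
            p.data[:] = 0
    pyramid = _tiny_head_inputs(rng, cfg)
    with nn.no_grad():
        feat, logits, boxes, _ = head.select_queries(
            nn.concat([p.reshape(1, cfg.d_model, -1).transpose(0, 2, 1)
                       for p in pyramid], axis=1),
            [(8, 8), (4, 4), (2, 2)], cfg.n_queries)
        out = head(pyramid)
    assert np.allclose(out["boxes"].data, boxes.data, atol=1e-6)


def test_output_box_count_equals_configured_queries(rng):
    cfg = HeadConfig(d_model=16, n_queries=12, depth=1, heads=2, ffn_dim=16)
    nn.seed_all(0)
    head = RTDETRHead(cfg)
    head.eval()
    with nn.no_grad():
        out = head(_tiny_head_inputs(rng, cfg))
    assert out["boxes"].shape == (1, 12, 4)
    assert out["logits"].shape == (1, 12, cfg.num_classes)


def test_inference_is_deterministic(rng):
    nn.seed_all(1)
    model = build_model(ModelConfig.smoke(), seed=3)
    x = Tensor(rng.standard_normal((1, 3, 96, 96)).astype(np.float32))
    d1 = model.detect(x, top=20)[0]
    d2 = model.detect(x, top=20)[0]
    assert np.array_equal(d1.boxes, d2.boxes)
    assert np.array_equal(d1.scores, d2.scores)
    assert np.array_equal(d1.classes, d2.classes)
    assert np.all(np.diff(d1.scores) <= 1e-9)        # confidence sorted
    assert d1.boxes.min() >= 0 and d1.boxes.max() <= 96


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def _perfect_outputs(targets, nq=6, nc=5):
    """Predictions that equal the targets exactly, high confidence."""
    n = len(targets)
    logits = np.full((n, nq, nc), -12.0)
    boxes = np.tile(np.array([0.5, 0.5, 0.05, 0.05]), (n, nq, 1))
    for i, t in enumerate(targets):
        for j, (b, c) in enumerate(zip(t["boxes"], t["classes"])):
            boxes[i, j] = b
            logits[i, j, c] = 12.0
    out = {"layers": [(Tensor(logits), Tensor(boxes))],
           "enc": (Tensor(logits), Tensor(boxes)),
           "dn_count": 0}
    return out


def test_box_loss_components_vanish_on_perfect_predictions():
    targets = [{"boxes": np.array([[0.4, 0.4, 0.2, 0.2], [0.7, 0.7, 0.1, 0.1]]),
                "classes": np.array([0, 3])}]
    _, comps = total_loss(_perfect_outputs(targets), targets, LossConfig())
    assert comps["l1"] == pytest.approx(0.0, abs=1e-6)
    assert comps["box"] == pytest.approx(0.0, abs=1e-4)


def test_swapping_box_loss_changes_only_iou_term():
    rng = np.random.default_rng(0)
    targets = [{"boxes": np.array([[0.4, 0.4, 0.2, 0.2]]),
                "classes": np.array([2])}]
    logits = rng.standard_normal((1, 5, 5))
    boxes = 1 / (1 + np.exp(-rng.standard_normal((1, 5, 4))))
    out = {"layers": [(Tensor(logits), Tensor(boxes))],
           "enc": (Tensor(logits.copy()), Tensor(boxes.copy())),
           "dn_count": 0}
    _, c_giou = total_loss(out, targets, LossConfig(box="giou"))
    _, c_inner = total_loss(out, targets, LossConfig(box="inner_eiou"))
    assert c_giou["class"] == pytest.approx(c_inner["class"], abs=1e-9)
    assert c_giou["l1"] == pytest.approx(c_inner["l1"], abs=1e-9)
    assert c_giou["box"] != pytest.approx(c_inner["box"], abs=1e-6)


def test_training_loss_gradient_is_finite(rng):
    nn.seed_all(2)
    model = build_model(ModelConfig.smoke(), seed=2)
    x = Tensor(rng.standard_normal((2, 3, 96, 96)).astype(np.float32))
    targets = [{"boxes": np.array([[0.5, 0.5, 0.3, 0.3]]), "classes": np.array([1])},
               {"boxes": np.array([[0.3, 0.6, 0.2, 0.2], [0.7, 0.2, 0.15, 0.2]]),
                "classes": np.array([0, 4])}]
    loss, comps = model.loss(x, targets, np.random.default_rng(0))
    assert np.isfinite(loss.data)
    loss.backward()
    grads = [p.grad for p in model.parameters() if p.grad is not None]
    assert grads, "no gradients flowed"
    assert all(np.all(np.isfinite(g)) for g in grads)
    assert all(v >= 0 and np.isfinite(v) for v in comps.values())
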