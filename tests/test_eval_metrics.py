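"""Detection-metric tests: greedy matching, AP staircase oracle, confusion
matrix bookkeeping and ranking monotonicity."""

import itertools

import numpy as np
import pytest

from ripedetr.detr_head import DetectionSet
from ripedetr.eval_metrics import (average_precision, confusion_matrix,
                                   iou_matrix, map_suite, match_detections,
                                   TimingReport)
from ripedetr.synthetic_data import LabeledBox


def _det(boxes, classes, scores):
    order = np.argsort(-np.asarray(scores), kind="stable")
    return DetectionSet(boxes=np.asarray(boxes, float)[order],
                        classes=np.asarray(classes)[order],
                        scores=np.asarray(scores, float)[order])


def _gt(boxes, classes):
    return [LabeledBox(*b, cls=c) for b, c in zip(boxes, classes)]


PERFECT_GT = _gt([(10, 10, 50, 50), (60, 60, 100, 100)], [0, 2])
PERFECT_DET = _det([(10, 10, 50, 50), (60, 60, 100, 100)], [0, 2], [0.9, 0.8])


def test_perfect_predictions_are_all_true_positives():
    flags = match_detections(PERFECT_DET, PERFECT_GT, 0.5)
    assert flags.tolist() == [True, True]


def test_duplicate_detection_counts_one_tp_one_fp():
    dets = _det([(10, 10, 50, 50), (11, 11, 51, 51)], [0, 0], [0.9, 0.8])
    gts = _gt([(10, 10, 50, 50)], [0])
    flags = match_detections(dets, gts, 0.5)
    assert flags.sum() == 1 and flags[0]


def test_class_mismatch_is_a_false_positive():
    dets = _det([(10, 10, 50, 50)], [1], [0.9])
    assert match_detections(dets, _gt([(10, 10, 50, 50)], [0]), 0.5).sum() == 0


def test_greedy_matching_matches_enumeration_oracle(rng):
    """The greedy-by-confidence TP count equals the oracle that enumerates
    all one-to-one assignments while respecting the confidence-priority
    rule (higher-confidence detections claim their best IoU first)."""
    for _ in range(20):
        n_det, n_gt = int(rng.integers(1, 5)), int(rng.integers(1, 4))
        xy = rng.uniform(0, 80, (n_det, 2))
        wh = rng.uniform(12, 40, (n_det, 2))
        det_boxes = np.concatenate([xy, xy + wh], axis=1)
        gt_boxes = det_boxes[rng.integers(0, n_det, n_gt)] + rng.uniform(-3, 3, (n_gt, 4))
        dets = _det(det_boxes, np.zeros(n_det, int), rng.uniform(0.1, 1, n_det))
        gts = _gt(gt_boxes, np.zeros(n_gt, int))
        flags = match_detections(dets, gts, 0.5)

        ious = iou_matrix(dets.boxes, gt_boxes)
        taken = set()
        ref = 0
        for i in range(n_det):  # confidence order
            cands = [(ious[i, j], j) for j in range(n_gt)
                     if j not in taken and ious[i, j] >= 0.5]
            if cands:
                taken.add(max(cands)[1])
                ref += 1
        assert flags.sum() == ref


def test_unsorted_detections_rejected():
    bad = DetectionSet(boxes=np.zeros((2, 4)), classes=np.zeros(2, int),
                       scores=np.array([0.1, 0.9]))
    with pytest.raises(ValueError):
        match_detections(bad, PERFECT_GT)


# ---------------------------------------------------------------------------
# AP
# ---------------------------------------------------------------------------

def test_perfect_run_gives_ap_one():
    flags = np.array([True, True])
    assert average_precision(flags, np.array([0.9, 0.8]), 2) == pytest.approx(1.0)


def test_no_predictions_gives_ap_zero():
    assert average_precision(np.zeros(0, bool), np.zeros(0), 3) == 0.0


def test_ap_matches_hand_enumerated_staircase():
    """3 detections / 2 ground truths: [TP 0.9, FP 0.8, TP 0.7].

    Precision-recall points: (0.5, 1), (0.5, 1/2), (1.0, 2/3); the
    right-max envelope is 1 for r <= 0.5 and 2/3 above, so the 101-point
    integral is (51*1 + 50*(2/3)) / 101.
    """
    flags = np.array([True, False, True])
    scores = np.array([0.9, 0.8, 0.7])
    expect = (51 * 1.0 + 50 * (2 / 3)) / 101
    assert average_precision(flags, scores, 2) == pytest.approx(expect, abs=1e-12)


def test_removing_a_false_positive_never_decreases_ap(rng):
    for _ in range(20):
        n = int(rng.integers(3, 10))
        flags = rng.random(n) < 0.5
        scores = rng.uniform(0, 1, n)
        n_gt = max(int(flags.sum()), 1)
        base = average_precision(flags, scores, n_gt)
        fps = np.where(~flags)[0]
        if not fps.size:
            continue
        drop = fps[rng.integers(len(fps))]
        keep = np.ones(n, bool)
        keep[drop] = False
        assert average_precision(flags[keep], scores[keep], n_gt) >= base - 1e-12


def test_map50_upper_bounds_map5095():
    dets = [_det([(10, 10, 50, 50), (58, 62, 104, 98)], [0, 2], [0.9, 0.8])]
    gts = [PERFECT_GT]
    with np.errstate(all="ignore"):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = map_suite(dets, gts)
    assert rep.map50 >= rep.map50_95 - 1e-12
    assert 0 <= rep.map50 <= 1 and 0 <= rep.f1 <= 1


def test_map_suite_perfect_detections():
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = map_suite([PERFECT_DET], [PERFECT_GT])
    assert rep.map50 == pytest.approx(1.0)
    assert rep.map50_95 == pytest.approx(1.0)  # boxes coincide exactly
    assert rep.precision == pytest.approx(1.0)
    assert rep.recall == pytest.approx(1.0)
    assert rep.f1 == pytest.approx(1.0)


def test_class_without_ground_truth_warns_and_is_excluded():
    with pytest.warns(RuntimeWarning, match="without ground truth"):
        rep = map_suite([PERFECT_DET], [PERFECT_GT])
    assert set(rep.ap50) == {0, 2}


# ---------------------------------------------------------------------------
# confusion matrix
# ---------------------------------------------------------------------------

def test_confusion_matrix_diagonal_for_perfect_predictions():
    mat = confusion_matrix([PERFECT_DET], [PERFECT_GT], 0.5, 0.5)
    assert mat[0, 0] == 1 and mat[2, 2] == 1
    assert mat.sum() == 2


def test_confusion_matrix_class_swap_has_zero_diagonal():
    dets = _det([(10, 10, 50, 50), (60, 60, 100, 100)], [2, 0], [0.9, 0.8])
    mat = confusion_matrix([dets], [PERFECT_GT], 0.5, 0.5)
    assert mat[0, 0] == 0 and mat[2, 2] == 0
    assert mat[2, 0] == 1 and mat[0, 2] == 1


def test_confusion_matrix_column_sums_equal_gt_counts(rng):
    gts, dets = [], []
    for _ in range(5):
        n = int(rng.integers(1, 5))
        boxes = np.concatenate([rng.uniform(0, 60, (n, 2)),
                                rng.uniform(70, 120, (n, 2))], axis=1)
        cls = rng.integers(0, 5, n)
        gts.append(_gt(boxes, cls))
        m = int(rng.integers(0, 4))
        db = np.concatenate([rng.uniform(0, 60, (m, 2)),
                             rng.uniform(70, 120, (m, 2))], axis=1)
        dets.append(_det(db, rng.integers(0, 5, m), rng.uniform(0.3, 1, m)))
    mat = confusion_matrix(dets, gts, 0.5, 0.0)
    col = mat.sum(axis=0)
    for c in range(5):
        expect = sum(1 for g in gts for b in g if b.cls == c)
        assert col[c] == expect


def test_fps_timing_identity():
    rep = TimingReport(t_avg=0.04)
    assert rep.fps * rep.t_avg == pytest.approx(1.0)
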