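"""Detection evaluation: precision/recall/F1, per-class AP, mAP50,
mAP50:95, confusion matrix and a wall-clock FPS harness.

Matching is the standard greedy rule: detections are visited in order of
descending confidence and claim the best still-unmatched ground truth of
the same class with IoU above the threshold.  AP integrates the
precision-recall staircase by 101-point interpolation; mAP averages
per-class APs (classes without ground truth are excluded, with a
warning).  P/R/F1 are reported at the confidence threshold that maximises
(macro-averaged) F1.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .detr_head import DetectionSet
from .synthetic_data import LabeledBox

__all__ = [
    "PRPoint",
    "EvalReport",
    "TimingReport",
    "iou_matrix",
    "match_detections",
    "average_precision",
    "map_suite",
    "confusion_matrix",
    "time_inference",
]

IOU_THRESHOLDS_5095 = np.arange(0.50, 0.96, 0.05)


@dataclass
class PRPoint:
    threshold: float
    tp: int
    fp: int
    fn: int

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 0.0


@dataclass
class EvalReport:
    ap50: Dict[int, float]
    map50: float
    map50_95: float
    precision: float
    recall: float
    f1: float
    threshold: float
    n_classes: int
    confusion: np.ndarray = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "map50": self.map50,
            "map50_95": self.map50_95,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "threshold": self.threshold,
            "ap50": {int(k): float(v) for k, v in self.ap50.items()},
            "confusion": self.confusion.tolist() if self.confusion is not None else None,
        }


@dataclass
class TimingReport:
    t_avg: float

    @property
    def fps(self) -> float:
        return 1.0 / self.t_avg


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU of (n,4) and (m,4) xyxy boxes."""
    a = np.asarray(a, dtype=np.float64).reshape(-1, 4)
    b = np.asarray(b, dtype=np.float64).reshape(-1, 4)
    lt = np.maximum(a[:, None, :2], b[None, :, :2])
    rb = np.minimum(a[:, None, 2:], b[None, :, 2:])
    wh = np.clip(rb - lt, 0, None)
    inter = wh[..., 0] * wh[..., 1]
    area_a = np.clip(a[:, 2] - a[:, 0], 0, None) * np.clip(a[:, 3] - a[:, 1], 0, None)
    area_b = np.clip(b[:, 2] - b[:, 0], 0, None) * np.clip(b[:, 3] - b[:, 1], 0, None)
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def _boxes_of(gts: Sequence[LabeledBox]) -> np.ndarray:
    if not gts:
        return np.zeros((0, 4))
    return np.stack([g.as_array() for g in gts])


def match_detections(dets: DetectionSet, gts: Sequence[LabeledBox],
                     iou_thr: float = 0.5) -> np.ndarray:
    """Boolean TP flag per detection (greedy, each ground truth claimed at
    most once, same-class only).  Detections must be confidence-sorted."""
    n = len(dets.scores)
    flags = np.zeros(n, dtype=bool)
    if n == 0 or not gts:
        return flags
    if np.any(np.diff(dets.scores) > 1e-9):
        raise ValueError("detections must be sorted by descending confidence")
    gt_boxes = _boxes_of(gts)
    gt_cls = np.array([g.cls for g in gts])
    ious = iou_matrix(dets.boxes, gt_boxes)
    taken = np.zeros(len(gts), dtype=bool)
    for i in range(n):
        cand = np.where((gt_cls == dets.classes[i]) & ~taken
                        & (ious[i] >= iou_thr))[0]
        if cand.size:
            j = cand[np.argmax(ious[i, cand])]
            taken[j] = True
            flags[i] = True
    return flags


def average_precision(tp_flags: np.ndarray, scores: np.ndarray,
                      n_gt: int) -> float:
    """101-point interpolated AP from per-detection TP flags."""
    if n_gt == 0:
        return float("nan")
    if len(tp_flags) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = np.asarray(tp_flags, dtype=np.float64)[order]
    cum_tp = np.cumsum(tp)
    cum_fp = np.cumsum(1.0 - tp)
    recall = cum_tp / n_gt
    precision = cum_tp / np.maximum(cum_tp + cum_fp, 1e-12)
    # precision envelope, then sample at 101 recall points
    env = np.maximum.accumulate(precision[::-1])[::-1]
    out = 0.0
    for r in np.linspace(0, 1, 101):
        mask = recall >= r - 1e-12
        out += env[mask].max() if mask.any() else 0.0
    return out / 101.0


def _per_class_flags(all_dets: Sequence[DetectionSet],
                     all_gts: Sequence[Sequence[LabeledBox]],
                     cls: int, iou_thr: float):
    flags, scores = [], []
    n_gt = 0
    for dets, gts in zip(all_dets, all_gts):
        keep = dets.classes == cls
        sub = DetectionSet(boxes=dets.boxes[keep], classes=dets.classes[keep],
                           scores=dets.scores[keep])
        gsub = [g for g in gts if g.cls == cls]
        n_gt += len(gsub)
        f = match_detections(sub, gsub, iou_thr)
        flags.append(f)
        scores.append(sub.scores)
    return (np.concatenate(flags) if flags else np.zeros(0, bool),
            np.concatenate(scores) if scores else np.zeros(0),
            n_gt)


def map_suite(all_dets: Sequence[DetectionSet],
              all_gts: Sequence[Sequence[LabeledBox]],
              num_classes: int = 5) -> EvalReport:
    """Full evaluation over a dataset of images."""
    present = sorted({g.cls for gts in all_gts for g in gts})
    skipped = [c for c in range(num_classes) if c not in present]
    if skipped:
        warnings.warn(f"classes without ground truth excluded from mAP: {skipped}",
                      RuntimeWarning, stacklevel=2)
    ap50: Dict[int, float] = {}
    ap_all: Dict[int, List[float]] = {c: [] for c in present}
    for thr in IOU_THRESHOLDS_5095:
        for c in present:
            f, s, n_gt = _per_class_flags(all_dets, all_gts, c, float(thr))
            ap = average_precision(f, s, n_gt)
            ap_all[c].append(ap)
            if abs(thr - 0.5) < 1e-9:
                ap50[c] = ap
    map50 = float(np.mean([ap50[c] for c in present])) if present else 0.0
    map5095 = float(np.mean([np.mean(ap_all[c]) for c in present])) if present else 0.0

    # macro P/R/F1 at the F1-maximising confidence threshold
    best = (0.0, 0.0, 0.0, 0.0)  # f1, p, r, thr
    for thr in np.linspace(0.05, 0.95, 19):
        ps, rs = [], []
        for c in present:
            tp = fp = fn = 0
            for dets, gts in zip(all_dets, all_gts):
                keep = (dets.classes == c) & (dets.scores >= thr)
                sub = DetectionSet(boxes=dets.boxes[keep],
                                   classes=dets.classes[keep],
                                   scores=dets.scores[keep])
                gsub = [g for g in gts if g.cls == c]
                f = match_detections(sub, gsub, 0.5)
                tp += int(f.sum())
                fp += int((~f).sum())
                fn += len(gsub) - int(f.sum())
            ps.append(tp / (tp + fp) if tp + fp else 0.0)
            rs.append(tp / (tp + fn) if tp + fn else 0.0)
        p, r = float(np.mean(ps)), float(np.mean(rs))
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        if f1 > best[0]:
            best = (f1, p, r, float(thr))
    f1, p, r, thr = best
    conf = confusion_matrix(all_dets, all_gts, 0.5, thr, num_classes)
    return EvalReport(ap50=ap50, map50=map50, map50_95=map5095,
                      precision=p, recall=r, f1=f1, threshold=thr,
                      n_classes=num_classes, confusion=conf)


def confusion_matrix(all_dets: Sequence[DetectionSet],
                     all_gts: Sequence[Sequence[LabeledBox]],
                     iou_thr: float = 0.5, conf_thr: float = 0.25,
                     num_classes: int = 5) -> np.ndarray:
    """(S+1)x(S+1) counts; rows = predicted class (+background), columns =
    true class (+background).  Unmatched detections land in the background
    column, missed ground truths in the background row."""
    S = num_classes
    mat = np.zeros((S + 1, S + 1), dtype=int)
    for dets, gts in zip(all_dets, all_gts):
        keep = dets.scores >= conf_thr
        boxes, cls = dets.boxes[keep], dets.classes[keep]
        gt_boxes = _boxes_of(gts)
        gt_cls = np.array([g.cls for g in gts], dtype=int)
        taken = np.zeros(len(gts), dtype=bool)
        if len(boxes) and len(gts):
            ious = iou_matrix(boxes, gt_boxes)
        for i in range(len(boxes)):
            j_best = -1
            if len(gts):
                cand = np.where(~taken & (ious[i] >= iou_thr))[0]
                if cand.size:
                    j_best = cand[np.argmax(ious[i, cand])]
            if j_best >= 0:
                taken[j_best] = True
                mat[cls[i], gt_cls[j_best]] += 1
            else:
                mat[cls[i], S] += 1
        for j in np.where(~taken)[0]:
            mat[S, gt_cls[j]] += 1
    return mat


def time_inference(model, images: Sequence[np.ndarray], warmup: int = 1,
                   reps: int = 3) -> TimingReport:
    """Mean wall-clock seconds per image after warm-up (hardware-dependent;
    reported for information only)."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    from . import nn

    def run(img):
        x = nn.Tensor(np.asarray(img, dtype=np.float32).transpose(2, 0, 1)[None] / 255.0)
        model.detect(x)

    for _ in range(warmup):
        run(images[0])
    t0 = time.perf_counter()
    count = 0
    for _ in range(reps):
        for img in images:
            run(img)
            count += 1
    return TimingReport(t_avg=(time.perf_counter() - t0) / count)
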