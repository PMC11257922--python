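"""IoU-family bounding-box regression losses.

The family: plain IoU, GIoU (the RT-DETR baseline regression term), the
EIoU decomposition into overlap + centre-distance + width/height terms, the
Inner-IoU auxiliary-box construction (both boxes shrunk or grown about
their own centres by a scale ``ratio``), and their combination

    L_Inner-EIoU = L_EIoU + IoU - IoU_inner

which at ``ratio = 1`` reduces exactly to L_EIoU.  The auxiliary box grants
extra gradient signal for high-overlap pairs when ``ratio < 1`` (the
default 0.70 is the sweep optimum reported for this detector family).

All functions accept boxes as ``(..., 4)`` arrays (or autodiff tensors) in
``x1, y1, x2, y2`` order and are fully vectorised; they are used both as
plain numpy scoring functions and, on tensors, as differentiable training
losses.  Conversion to centre/size form happens in exactly one place to
avoid convention drift.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .nn.core import Tensor

__all__ = [
    "EIoUComponents",
    "iou",
    "giou",
    "inner_iou",
    "eiou",
    "inner_eiou",
    "DEFAULT_INNER_RATIO",
    "INNER_RATIO_SWEEP",
]

DEFAULT_INNER_RATIO = 0.70
#: auxiliary-box scale factors explored for this detector family
INNER_RATIO_SWEEP = (0.70, 0.75, 0.80, 1.10, 1.13, 1.15)

_EPS = 1e-9


def _wrap(a):
    return a if isinstance(a, Tensor) else Tensor(np.asarray(a, dtype=np.float64))


def _maybe_unwrap(result: Tensor, *inputs):
    if any(isinstance(x, Tensor) for x in inputs):
        return result
    out = result.data
    return float(out) if out.ndim == 0 else out


def _split(box: Tensor):
    return box[..., 0], box[..., 1], box[..., 2], box[..., 3]


def _to_cxcywh(box: Tensor):
    """The single xyxy -> centre/size conversion point."""
    x1, y1, x2, y2 = _split(box)
    return (x1 + x2) * 0.5, (y1 + y2) * 0.5, x2 - x1, y2 - y1


def _check_degenerate(*boxes) -> None:
    for b in boxes:
        data = b.data if isinstance(b, Tensor) else np.asarray(b)
        w = data[..., 2] - data[..., 0]
        h = data[..., 3] - data[..., 1]
        if np.any(w <= 0) or np.any(h <= 0):
            warnings.warn("degenerate (zero-area) box; intersection terms are clamped",
                          RuntimeWarning, stacklevel=3)
            return


def _pairwise_iou(a: Tensor, b: Tensor):
    ax1, ay1, ax2, ay2 = _split(a)
    bx1, by1, bx2, by2 = _split(b)
    iw = (ax2.minimum(bx2) - ax1.maximum(bx1)).clamp(lo=0.0)
    ih = (ay2.minimum(by2) - ay1.maximum(by1)).clamp(lo=0.0)
    inter = iw * ih
    area_a = (ax2 - ax1).clamp(lo=0.0) * (ay2 - ay1).clamp(lo=0.0)
    area_b = (bx2 - bx1).clamp(lo=0.0) * (by2 - by1).clamp(lo=0.0)
    union = area_a + area_b - inter
    return inter / (union + _EPS), union


def iou(a, b):
    """Intersection over union of axis-aligned boxes, in [0, 1]."""
    _check_degenerate(a, b)
    at, bt = _wrap(a), _wrap(b)
    val, _ = _pairwise_iou(at, bt)
    return _maybe_unwrap(val, a, b)


def giou(a, b):
    """Generalised IoU: IoU minus the enclosing-box penalty, in (-1, 1]."""
    _check_degenerate(a, b)
    at, bt = _wrap(a), _wrap(b)
    val, union = _pairwise_iou(at, bt)
    ax1, ay1, ax2, ay2 = _split(at)
    bx1, by1, bx2, by2 = _split(bt)
    cw = ax2.maximum(bx2) - ax1.minimum(bx1)
    ch = ay2.maximum(by2) - ay1.minimum(by1)
    hull = cw * ch
    out = val - (hull - union) / (hull + _EPS)
    return _maybe_unwrap(out, a, b)


def _inner_boxes(box: Tensor, ratio: float):
    cx, cy, w, h = _to_cxcywh(box)
    hw, hh = w * (0.5 * ratio), h * (0.5 * ratio)
    return cx - hw, cy - hh, cx + hw, cy + hh


def inner_iou(a, b, ratio: float = DEFAULT_INNER_RATIO):
    """IoU of the centre-shared auxiliary boxes scaled by ``ratio``.

    Intersection is clamped at zero when the shrunken boxes separate; the
    union uses the ``(ratio)**2``-scaled areas, so ``ratio = 1`` gives the
    ordinary IoU for any pair.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    _check_degenerate(a, b)
    at, bt = _wrap(a), _wrap(b)
    al, at_, ar, ab_ = _inner_boxes(at, ratio)
    bl, bt_, br, bb = _inner_boxes(bt, ratio)
    iw = (ar.minimum(br) - al.maximum(bl)).clamp(lo=0.0)
    ih = (ab_.minimum(bb) - at_.maximum(bt_)).clamp(lo=0.0)
    inter = iw * ih
    _, _, aw, ah = _to_cxcywh(at)
    _, _, bw, bh = _to_cxcywh(bt)
    union = (aw * ah) * ratio ** 2 + (bw * bh) * ratio ** 2 - inter
    out = inter / (union + _EPS)
    return _maybe_unwrap(out, a, b)


@dataclass
class EIoUComponents:
    """The three non-negative parts of the EIoU loss; all vanish iff the
    boxes coincide."""

    l_iou: object
    l_dis: object
    l_asp: object

    @property
    def total(self):
        return self.l_iou + self.l_dis + self.l_asp


def eiou(a, b, return_components: bool = False):
    """EIoU loss: (1 - IoU) + centre-distance term + width/height term.

    The centre term is the squared centre offset over the squared diagonal
    of the smallest enclosing box; the aspect term is the squared width and
    height differences over the squared enclosing width and height.
    """
    _check_degenerate(a, b)
    at, bt = _wrap(a), _wrap(b)
    val, _ = _pairwise_iou(at, bt)
    acx, acy, aw, ah = _to_cxcywh(at)
    bcx, bcy, bw, bh = _to_cxcywh(bt)
    ax1, ay1, ax2, ay2 = _split(at)
    bx1, by1, bx2, by2 = _split(bt)
    cw = ax2.maximum(bx2) - ax1.minimum(bx1)
    ch = ay2.maximum(by2) - ay1.minimum(by1)
    l_iou = 1.0 - val
    l_dis = ((acx - bcx) ** 2 + (acy - bcy) ** 2) / (cw ** 2 + ch ** 2 + _EPS)
    l_asp = (aw - bw) ** 2 / (cw ** 2 + _EPS) + (ah - bh) ** 2 / (ch ** 2 + _EPS)
    comp = EIoUComponents(
        _maybe_unwrap(l_iou, a, b),
        _maybe_unwrap(l_dis, a, b),
        _maybe_unwrap(l_asp, a, b),
    )
    if return_components:
        return comp
    return comp.total


def inner_eiou(a, b, ratio: float = DEFAULT_INNER_RATIO):
    """Inner-EIoU loss: ``L_EIoU + IoU - IoU_inner``.

    With ``ratio = 1`` the correction cancels and the value equals the
    plain EIoU loss.
    """
    return eiou(a, b) + iou(a, b) - inner_iou(a, b, ratio=ratio)
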