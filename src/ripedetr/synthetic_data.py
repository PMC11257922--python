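"""Synthetic ripeness-scene generation, augmentation, splitting and
annotation export.

Scenes emulate outdoor fruit photography: multi-fruit images with
class-dependent coloration (five ripeness stages from bright-green unripe
through red ripe to dark, blemished rotten), green leaf occluders,
sun/shade/overcast lighting, and overlapping fruit.  Fruits are rendered
as shaded ellipses with a radial gradient and a specular highlight; leaves
as elongated green blobs.  Every operation is a pure function of its
inputs and seed, so downstream modules are testable without any external
download.

Augmentations mirror common field-dataset preprocessing: mean blur with
kernel sizes 5..15, random crops keeping 40-80 % of the image, and random
rotations within +/-60 degrees, with all outputs resized to 640x640 and
boxes transformed alongside (boxes retaining less than a quarter of their
original visible area are dropped).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import yaml
from matplotlib.colors import hsv_to_rgb
from PIL import Image
from scipy import ndimage
from shapely.geometry import Polygon, box as shapely_box

__all__ = [
    "RipenessClass",
    "LabeledBox",
    "SceneSpec",
    "SplitSpec",
    "Sample",
    "DEFAULT_CLASSES",
    "CLASS_NAMES",
    "PlacementError",
    "generate_scene",
    "classify_mean_hue",
    "augment",
    "split_dataset",
    "write_dataset",
    "read_coco",
    "read_yolo",
    "make_dataset",
]

AUGMENT_OPS = ("mean_blur", "random_crop", "random_rotate")
BLUR_KERNELS = (5, 7, 9, 11, 13, 15)
CROP_RANGE = (0.40, 0.80)
ROTATE_RANGE = (-60.0, 60.0)
BOX_SURVIVAL_FLOOR = 0.25
CANONICAL_SIZE = 640


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RipenessClass:
    """One visual maturity stage.

    ``hue_profile`` is ((h_lo, h_hi), (s_lo, s_hi), (v_lo, v_hi)) in [0, 1];
    the hue interval may wrap past 1 (reds).  ``spot_rate`` is the expected
    number of dark blemishes per fruit (rotten only).
    """

    id: int
    name: str
    hue_profile: Tuple[Tuple[float, float], ...]
    spot_rate: float = 0.0

    @property
    def hue_center(self) -> float:
        lo, hi = self.hue_profile[0]
        return ((lo + hi) / 2.0) % 1.0


#: Bright green -> yellow/pink -> uniform red -> dull deep red -> dark brown.
DEFAULT_CLASSES = (
    RipenessClass(0, "unripe", ((0.26, 0.36), (0.55, 0.85), (0.55, 0.85))),
    RipenessClass(1, "half_ripe", ((0.105, 0.16), (0.60, 0.90), (0.60, 0.90))),
    RipenessClass(2, "ripe", ((0.975, 1.045), (0.80, 1.00), (0.65, 0.90))),
    RipenessClass(3, "overripe", ((0.90, 0.96), (0.70, 0.95), (0.45, 0.60))),
    RipenessClass(4, "rotten", ((0.055, 0.095), (0.50, 0.80), (0.25, 0.40)),
                  spot_rate=4.0),
)
CLASS_NAMES = tuple(c.name for c in DEFAULT_CLASSES)

LIGHTING = {"sun": 1.15, "overcast": 0.85, "shade": 0.65}


@dataclass
class LabeledBox:
    """Axis-aligned box in pixel coordinates (origin top-left) + class id."""

    x1: float
    y1: float
    x2: float
    y2: float
    cls: int

    def __post_init__(self):
        if not (self.x1 < self.x2 and self.y1 < self.y2):
            raise ValueError(f"invalid box {(self.x1, self.y1, self.x2, self.y2)}")

    @property
    def area(self) -> float:
        return (self.x2 - self.x1) * (self.y2 - self.y1)

    def as_array(self) -> np.ndarray:
        return np.array([self.x1, self.y1, self.x2, self.y2], dtype=np.float64)


@dataclass
class SceneSpec:
    image_size: int = CANONICAL_SIZE
    n_fruits: int = 5
    occlusion_prob: float = 0.3
    lighting: str = "overcast"
    seed: int = 0

    def __post_init__(self):
        if self.n_fruits < 1:
            raise ValueError("n_fruits must be >= 1")
        if not 0.0 <= self.occlusion_prob <= 1.0:
            raise ValueError("occlusion_prob must be in [0, 1]")
        if self.lighting not in LIGHTING:
            raise ValueError(f"lighting must be one of {sorted(LIGHTING)}")


@dataclass
class SplitSpec:
    fractions: Tuple[float, float, float] = (0.70, 0.10, 0.20)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class Sample:
    image: np.ndarray                 # (H, W, 3) uint8
    boxes: List[LabeledBox] = field(default_factory=list)
    id: Optional[int] = None


class PlacementError(RuntimeError):
    """The requested number of fruits cannot be placed in the image."""


# ---------------------------------------------------------------------------
# scene rendering
# ---------------------------------------------------------------------------

def _sample_range(rng, lo, hi):
    return rng.uniform(lo, hi)


def _scene_layout(spec: SceneSpec, classes: Sequence[RipenessClass],
                  force_class: Optional[int] = None) -> dict:
    """Sample the geometric/colour layout of a scene (no rasterisation).

    Exposed for statistical self-tests; :func:`generate_scene` renders it.
    """
    rng = np.random.default_rng(spec.seed)
    S = spec.image_size
    r_lo, r_hi = 0.055 * S, 0.11 * S
    if 2 * r_hi >= S:
        raise PlacementError(f"image size {S} too small for fruit radius {r_hi:.0f}")
    fruits = []
    attempts = 0
    max_attempts = 200 * spec.n_fruits
    while len(fruits) < spec.n_fruits:
        attempts += 1
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {spec.n_fruits} fruits in a {S}x{S} image")
        rx = _sample_range(rng, r_lo, r_hi)
        ry = rx * _sample_range(rng, 0.85, 1.1)
        cx = _sample_range(rng, rx, S - rx)
        cy = _sample_range(rng, ry, S - ry)
        ok = True
        for f in fruits:
            d = np.hypot(cx - f["cx"], cy - f["cy"])
            if d < 0.75 * (max(rx, ry) + max(f["rx"], f["ry"])):
                ok = False
                break
        if not ok:
            continue
        cls = (classes[force_class] if force_class is not None
               else classes[rng.integers(len(classes))])
        (h_lo, h_hi), (s_lo, s_hi), (v_lo, v_hi) = cls.hue_profile
        hue = _sample_range(rng, h_lo, h_hi) % 1.0
        sat = _sample_range(rng, s_lo, s_hi)
        val = _sample_range(rng, v_lo, v_hi)
        n_spots = rng.poisson(cls.spot_rate) if cls.spot_rate > 0 else 0
        spots = []
        for _ in range(n_spots):
            ang = rng.uniform(0, 2 * np.pi)
            rad = rng.uniform(0, 0.6)
            spots.append({
                "cx": cx + rad * rx * np.cos(ang),
                "cy": cy + rad * ry * np.sin(ang),
                "r": rng.uniform(0.08, 0.2) * rx,
            })
        occluded = bool(rng.random() < spec.occlusion_prob)
        leaf = None
        if occluded:
            ang = rng.uniform(0, 2 * np.pi)
            leaf = {
                "cx": cx + 0.9 * rx * np.cos(ang),
                "cy": cy + 0.9 * ry * np.sin(ang),
                "rx": rng.uniform(0.7, 1.0) * rx,
                "ry": rng.uniform(0.35, 0.55) * ry,
                "angle": rng.uniform(0, np.pi),
                "hue": rng.uniform(0.28, 0.34),
            }
        fruits.append({"cx": cx, "cy": cy, "rx": rx, "ry": ry,
                       "cls": cls.id, "hue": hue, "sat": sat, "val": val,
                       "spots": spots, "occluded": occluded, "leaf": leaf})
    bg_seed = int(rng.integers(2 ** 31))
    return {"fruits": fruits, "bg_seed": bg_seed}


def _background_hsv(S: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    cell = max(S // 16, 1)
    n = S // cell + 1
    h = rng.uniform(0.20, 0.34, (n, n))
    s = rng.uniform(0.25, 0.55, (n, n))
    v = rng.uniform(0.30, 0.55, (n, n))
    hsv = np.stack([h, s, v], axis=-1)
    hsv = np.kron(hsv, np.ones((cell, cell, 1)))[:S, :S]
    return ndimage.uniform_filter(hsv, size=(cell, cell, 1), mode="nearest")


def _ellipse_mask(X, Y, cx, cy, rx, ry, angle: float = 0.0):
    dx, dy = X - cx, Y - cy
    if angle:
        ca, sa = np.cos(angle), np.sin(angle)
        dx, dy = ca * dx + sa * dy, -sa * dx + ca * dy
    r2 = (dx / rx) ** 2 + (dy / ry) ** 2
    return r2


def generate_scene(spec: SceneSpec,
                   classes: Sequence[RipenessClass] = DEFAULT_CLASSES,
                   force_class: Optional[int] = None):
    """Render one scene.  Returns (image uint8 (S,S,3), list of LabeledBox).

    Deterministic: the same spec yields byte-identical output.  Fruits are
    at least ~50 % visible by construction (leaf occluders are anchored on
    the fruit rim and no larger than the fruit), comfortably above the
    20 %-visibility contract.
    """
    layout = _scene_layout(spec, classes, force_class)
    S = spec.image_size
    hsv = _background_hsv(S, layout["bg_seed"])
    Y, X = np.mgrid[0:S, 0:S].astype(np.float64)
    Y += 0.5
    X += 0.5
    light = LIGHTING[spec.lighting]
    boxes = []
    for f in layout["fruits"]:
        r2 = _ellipse_mask(X, Y, f["cx"], f["cy"], f["rx"], f["ry"])
        mask = r2 <= 1.0
        shade = 0.60 + 0.40 * np.clip(1.0 - r2, 0, 1)
        v = np.clip(f["val"] * shade * light, 0, 1)
        # specular highlight towards the light source (upper-left)
        hl = np.exp(-(((X - (f["cx"] - 0.35 * f["rx"])) / (0.35 * f["rx"])) ** 2
                      + ((Y - (f["cy"] - 0.35 * f["ry"])) / (0.35 * f["ry"])) ** 2))
        v = np.clip(v + 0.25 * hl, 0, 1)
        s = np.clip(f["sat"] * (1.0 - 0.5 * hl), 0, 1)
        hsv[mask, 0] = f["hue"]
        hsv[mask, 1] = s[mask]
        hsv[mask, 2] = v[mask]
        for sp in f["spots"]:
            sr2 = _ellipse_mask(X, Y, sp["cx"], sp["cy"], sp["r"], sp["r"])
            smask = (sr2 <= 1.0) & mask
            hsv[smask, 2] *= 0.35
        x1, y1 = max(f["cx"] - f["rx"], 0.0), max(f["cy"] - f["ry"], 0.0)
        x2, y2 = min(f["cx"] + f["rx"], S), min(f["cy"] + f["ry"], S)
        boxes.append(LabeledBox(x1, y1, x2, y2, f["cls"]))
    for f in layout["fruits"]:
        if f["leaf"] is None:
            continue
        lf = f["leaf"]
        lr2 = _ellipse_mask(X, Y, lf["cx"], lf["cy"], lf["rx"], lf["ry"], lf["angle"])
        lmask = lr2 <= 1.0
        hsv[lmask, 0] = lf["hue"]
        hsv[lmask, 1] = 0.60
        hsv[lmask, 2] = np.clip(0.45 * (0.7 + 0.3 * (1 - lr2[lmask])) * light, 0, 1)
    rgb = (hsv_to_rgb(np.clip(hsv, 0, 1)) * 255.0).round().astype(np.uint8)
    return rgb, boxes


def classify_mean_hue(image: np.ndarray, bbox: LabeledBox,
                      classes: Sequence[RipenessClass] = DEFAULT_CLASSES) -> int:
    """Nearest-class prediction from the circular mean hue inside the box's
    inscribed ellipse (a generator self-consistency probe, not a model)."""
    import matplotlib.colors as mcolors
    S = image.shape[0]
    x1, y1, x2, y2 = (int(round(v)) for v in (bbox.x1, bbox.y1, bbox.x2, bbox.y2))
    patch = image[max(y1, 0):y2, max(x1, 0):x2].astype(np.float64) / 255.0
    hsv = mcolors.rgb_to_hsv(patch)
    h, w = hsv.shape[:2]
    Y, X = np.mgrid[0:h, 0:w].astype(np.float64)
    r2 = _ellipse_mask(X, Y, (w - 1) / 2, (h - 1) / 2, max(w / 2 - 1, 1), max(h / 2 - 1, 1))
    hues = hsv[r2 <= 0.55, 0]  # inner core, robust to rim/occluder pixels
    ang = hues * 2 * np.pi
    mean_hue = (np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) / (2 * np.pi)) % 1.0
    dists = []
    for c in classes:
        d = abs(mean_hue - c.hue_center)
        dists.append(min(d, 1 - d))
    return int(np.argmin(dists))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _resize_with_boxes(image: np.ndarray, boxes: List[LabeledBox],
                       out_size: int):
    h, w = image.shape[:2]
    if (h, w) == (out_size, out_size):
        return image, boxes
    pil = Image.fromarray(image).resize((out_size, out_size), Image.BILINEAR)
    sx, sy = out_size / w, out_size / h
    out_boxes = [LabeledBox(b.x1 * sx, b.y1 * sy, b.x2 * sx, b.y2 * sy, b.cls)
                 for b in boxes]
    return np.asarray(pil), out_boxes


def augment(image: np.ndarray, boxes: Sequence[LabeledBox], op_name: str,
            seed: int, out_size: int = CANONICAL_SIZE, *,
            kernel: Optional[int] = None, frac: Optional[float] = None,
            angle: Optional[float] = None):
    """Apply one augmentation; returns (image 640x640 uint8, surviving boxes).

    Parameters left as None are drawn from the seeded generator within the
    canonical bounds (blur kernel odd in 5..15, crop fraction 0.40..0.80 of
    each side, rotation angle -60..60 degrees); explicit values let tests
    pin the draw.
    """
    if op_name not in AUGMENT_OPS:
        raise ValueError(f"unknown augmentation {op_name!r}; expected one of {AUGMENT_OPS}")
    rng = np.random.default_rng(seed)
    boxes = list(boxes)
    h, w = image.shape[:2]

    if op_name == "mean_blur":
        k = int(kernel) if kernel is not None else int(rng.choice(BLUR_KERNELS))
        if k % 2 == 0 or not 5 <= k <= 15:
            raise ValueError("blur kernel must be odd and within 5..15")
        out = ndimage.uniform_filter(image.astype(np.float64),
                                     size=(k, k, 1), mode="nearest")
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
        return _resize_with_boxes(out, boxes, out_size)

    if op_name == "random_crop":
        f = float(frac) if frac is not None else rng.uniform(*CROP_RANGE)
        if not CROP_RANGE[0] <= f <= CROP_RANGE[1]:
            raise ValueError("crop fraction must be within 0.40..0.80")
        cw, ch = max(int(round(f * w)), 1), max(int(round(f * h)), 1)
        x0 = int(rng.integers(0, w - cw + 1))
        y0 = int(rng.integers(0, h - ch + 1))
        out = image[y0:y0 + ch, x0:x0 + cw]
        kept = []
        for b in boxes:
            nx1, ny1 = max(b.x1 - x0, 0.0), max(b.y1 - y0, 0.0)
            nx2, ny2 = min(b.x2 - x0, cw), min(b.y2 - y0, ch)
            if nx2 <= nx1 or ny2 <= ny1:
                continue
            if (nx2 - nx1) * (ny2 - ny1) < BOX_SURVIVAL_FLOOR * b.area:
                continue
            kept.append(LabeledBox(nx1, ny1, nx2, ny2, b.cls))
        return _resize_with_boxes(out, kept, out_size)

    # random_rotate
    a = float(angle) if angle is not None else rng.uniform(*ROTATE_RANGE)
    if not ROTATE_RANGE[0] <= a <= ROTATE_RANGE[1]:
        raise ValueError("rotation angle must be within -60..60 degrees")
    if a == 0.0:
        return _resize_with_boxes(image, boxes, out_size)
    out = ndimage.rotate(image, a, reshape=False, order=1,
                         mode="constant", cval=0)
    theta = np.deg2rad(a)
    # ndimage rotates content counter-clockwise in (row, col); in (x, y)
    # screen coordinates (y down) a content point maps through R(-theta)
    c = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    R = np.array([[np.cos(theta), np.sin(theta)],
                  [-np.sin(theta), np.cos(theta)]])
    img_rect = shapely_box(0.0, 0.0, float(w), float(h))
    kept = []
    for b in boxes:
        corners = np.array([[b.x1, b.y1], [b.x2, b.y1],
                            [b.x2, b.y2], [b.x1, b.y2]])
        rot = (corners - c) @ R.T + c
        poly = Polygon(rot)
        visible = poly.intersection(img_rect)
        if visible.is_empty or visible.area < BOX_SURVIVAL_FLOOR * b.area:
            continue
        vx1, vy1, vx2, vy2 = visible.bounds
        if vx2 - vx1 < 1e-6 or vy2 - vy1 < 1e-6:
            continue
        kept.append(LabeledBox(vx1, vy1, vx2, vy2, b.cls))
    return _resize_with_boxes(out, kept, out_size)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def split_dataset(n_items: int, spec: SplitSpec):
    """Shuffled 70/10/20 split: floor for train and val, remainder to test.

    Returns three disjoint index arrays whose union is a permutation of
    0..n-1; deterministic per seed.
    """
    if n_items < 3:
        raise ValueError("need at least 3 items to split")
    f_train, f_val, _ = spec.fractions
    n_train = int(np.floor(f_train * n_items))
    n_val = int(np.floor(f_val * n_items))
    perm = np.random.default_rng(spec.seed).permutation(n_items)
    return (perm[:n_train], perm[n_train:n_train + n_val], perm[n_train + n_val:])


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------

def _class_histogram(samples: Sequence[Sample]) -> dict:
    hist = {name: 0 for name in CLASS_NAMES}
    for s in samples:
        for b in s.boxes:
            hist[CLASS_NAMES[b.cls]] += 1
    return hist


def write_dataset(samples: Sequence[Sample], format: str, out_dir,
                  splits: Optional[dict] = None) -> dict:
    """Write images plus annotations; returns (and saves) a YAML manifest.

    ``format='coco_json'`` writes a single COCO detection JSON with the
    categories in fixed class order; ``format='yolo_labels'`` writes one
    normalised ``cls cx cy w h`` text file per image.
    """
    if format not in ("coco_json", "yolo_labels"):
        raise ValueError(f"unknown dataset format {format!r}")
    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    names = []
    for i, s in enumerate(samples):
        sid = s.id if s.id is not None else i
        name = f"scene_{sid:05d}.png"
        Image.fromarray(s.image).save(img_dir / name)
        names.append(name)

    if format == "coco_json":
        images, annotations = [], []
        aid = 1
        for i, (s, name) in enumerate(zip(samples, names)):
            h, w = s.image.shape[:2]
            images.append({"id": i, "file_name": f"images/{name}",
                           "width": w, "height": h})
            for b in s.boxes:
                annotations.append({
                    "id": aid, "image_id": i, "category_id": b.cls,
                    "bbox": [b.x1, b.y1, b.x2 - b.x1, b.y2 - b.y1],
                    "area": b.area, "iscrowd": 0,
                })
                aid += 1
        coco = {
            "images": images,
            "annotations": annotations,
            "categories": [{"id": c.id, "name": c.name} for c in DEFAULT_CLASSES],
        }
        with open(out / "annotations.json", "w") as fh:
            json.dump(coco, fh)
    else:
        lbl_dir = out / "labels"
        lbl_dir.mkdir(exist_ok=True)
        for s, name in zip(samples, names):
            h, w = s.image.shape[:2]
            lines = []
            for b in s.boxes:
                cx = (b.x1 + b.x2) / 2.0 / w
                cy = (b.y1 + b.y2) / 2.0 / h
                bw = (b.x2 - b.x1) / w
                bh = (b.y2 - b.y1) / h
                lines.append(f"{b.cls} {cx:.6f} {cy:.6f} {bw:.6f} {bh:.6f}")
            (lbl_dir / name.replace(".png", ".txt")).write_text(
                "\n".join(lines) + ("\n" if lines else ""))

    manifest = {
        "format": format,
        "classes": list(CLASS_NAMES),
        "n_images": len(samples),
        "images": names,
        "class_histogram": _class_histogram(samples),
    }
    if splits is not None:
        manifest["splits"] = {k: [int(i) for i in v] for k, v in splits.items()}
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh)
    return manifest


def read_coco(path) -> List[Sample]:
    """Round-trip reader for the COCO JSON written by :func:`write_dataset`."""
    path = Path(path)
    with open(path / "annotations.json") as fh:
        coco = json.load(fh)
    by_image = {im["id"]: [] for im in coco["images"]}
    for ann in coco["annotations"]:
        x, y, w, h = ann["bbox"]
        by_image[ann["image_id"]].append(LabeledBox(x, y, x + w, y + h,
                                                    ann["category_id"]))
    samples = []
    for im in coco["images"]:
        img = np.asarray(Image.open(path / im["file_name"]))
        samples.append(Sample(image=img, boxes=by_image[im["id"]], id=im["id"]))
    return samples


def read_yolo(path) -> List[Sample]:
    path = Path(path)
    samples = []
    for i, img_file in enumerate(sorted((path / "images").glob("*.png"))):
        img = np.asarray(Image.open(img_file))
        h, w = img.shape[:2]
        boxes = []
        lbl = path / "labels" / (img_file.stem + ".txt")
        if lbl.exists():
            for line in lbl.read_text().splitlines():
                if not line.strip():
                    continue
                c, cx, cy, bw, bh = line.split()
                cx, cy, bw, bh = (float(v) for v in (cx, cy, bw, bh))
                boxes.append(LabeledBox((cx - bw / 2) * w, (cy - bh / 2) * h,
                                        (cx + bw / 2) * w, (cy + bh / 2) * h,
                                        int(c)))
        samples.append(Sample(image=img, boxes=boxes, id=i))
    return samples


# ---------------------------------------------------------------------------
# convenience dataset factory
# ---------------------------------------------------------------------------

def make_dataset(n_scenes: int, image_size: int = CANONICAL_SIZE, seed: int = 0,
                 n_fruits: Tuple[int, int] = (2, 6), occlusion_prob: float = 0.3,
                 augment_prob: float = 0.3) -> List[Sample]:
    """Generate a list of scenes with per-sample augmentation on/off."""
    rng = np.random.default_rng(seed)
    lightings = list(LIGHTING)
    samples = []
    for i in range(n_scenes):
        spec = SceneSpec(
            image_size=image_size,
            n_fruits=int(rng.integers(n_fruits[0], n_fruits[1] + 1)),
            occlusion_prob=occlusion_prob,
            lighting=lightings[rng.integers(len(lightings))],
            seed=int(rng.integers(2 ** 31)),
        )
        img, boxes = generate_scene(spec)
        if rng.random() < augment_prob:
            op = AUGMENT_OPS[rng.integers(len(AUGMENT_OPS))]
            img, boxes = augment(img, boxes, op, int(rng.integers(2 ** 31)),
                                 out_size=image_size)
        samples.append(Sample(image=img, boxes=boxes, id=i))
    return samples
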