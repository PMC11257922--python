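"""Scene generator, augmentation, split and annotation-format tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ripedetr import synthetic_data as sd


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------

def test_scene_generation_is_deterministic():
    spec = sd.SceneSpec(image_size=192, n_fruits=3, occlusion_prob=0.5, seed=1)
    img1, boxes1 = sd.generate_scene(spec)
    img2, boxes2 = sd.generate_scene(spec)
    assert np.array_equal(img1, img2)
    assert [(b.x1, b.y1, b.x2, b.y2, b.cls) for b in boxes1] == \
           [(b.x1, b.y1, b.x2, b.y2, b.cls) for b in boxes2]
    img3, _ = sd.generate_scene(sd.SceneSpec(image_size=192, n_fruits=3,
                                             occlusion_prob=0.5, seed=2))
    assert not np.array_equal(img1, img3)


def test_single_unoccluded_fruit_has_class_hue():
    spec = sd.SceneSpec(image_size=192, n_fruits=1, occlusion_prob=0.0, seed=5)
    img, boxes = sd.generate_scene(spec, force_class=2)  # ripe
    assert len(boxes) == 1
    assert boxes[0].cls == 2
    assert sd.classify_mean_hue(img, boxes[0]) == 2


def test_boxes_are_valid_and_inside_image():
    for seed in range(5):
        spec = sd.SceneSpec(image_size=160, n_fruits=4, occlusion_prob=0.5, seed=seed)
        img, boxes = sd.generate_scene(spec)
        assert img.shape == (160, 160, 3) and img.dtype == np.uint8
        for b in boxes:
            assert 0 <= b.x1 < b.x2 <= 160
            assert 0 <= b.y1 < b.y2 <= 160


def test_placement_failure_is_explicit():
    with pytest.raises(sd.PlacementError):
        sd.generate_scene(sd.SceneSpec(image_size=96, n_fruits=400, seed=0))


def test_occlusion_rate_matches_bernoulli_probability():
    """Monte-Carlo: with occlusion_prob=0.5 the fraction of leaf-occluded
    fruits over 500 scenes lands in [0.4, 0.6]."""
    occluded = total = 0
    for seed in range(500):
        spec = sd.SceneSpec(image_size=192, n_fruits=3, occlusion_prob=0.5,
                            seed=seed)
        layout = sd._scene_layout(spec, sd.DEFAULT_CLASSES)
        for f in layout["fruits"]:
            occluded += f["occluded"]
            total += 1
    assert 0.4 <= occluded / total <= 0.6


def test_majority_hue_classifier_recovers_class():
    """Generator self-consistency: mean-hue nearest-class prediction is
    right on at least 95 % of unoccluded fruits."""
    ok = total = 0
    for seed in range(100):
        cls = seed % 5
        spec = sd.SceneSpec(image_size=160, n_fruits=1, occlusion_prob=0.0,
                            seed=900 + seed)
        img, boxes = sd.generate_scene(spec, force_class=cls)
        ok += sd.classify_mean_hue(img, boxes[0]) == cls
        total += 1
    assert ok / total >= 0.95


def test_exactly_five_classes_with_expected_names():
    assert len(sd.DEFAULT_CLASSES) == 5
    assert sd.CLASS_NAMES == ("unripe", "half_ripe", "ripe", "overripe", "rotten")
    # hue intervals are pairwise disjoint on the circle
    ivals = [(c.hue_profile[0][0] % 1.0, c.hue_profile[0][1]) for c in sd.DEFAULT_CLASSES]
    for i, (lo1, hi1) in enumerate(ivals):
        for lo2, hi2 in ivals[i + 1:]:
            pts = (np.linspace(lo1, hi1, 9) % 1.0)
            inside = ((pts - lo2) % 1.0) <= (hi2 - lo2)
            assert not inside.any()


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _toy_image_and_box():
    img = np.zeros((200, 200, 3), np.uint8)
    img[80:120, 60:100] = 200
    return img, sd.LabeledBox(60, 80, 100, 120, 1)


def test_zero_rotation_is_identity_up_to_resize():
    img, box = _toy_image_and_box()
    out, boxes = sd.augment(img, [box], "random_rotate", seed=0, angle=0.0,
                            out_size=200)
    assert np.array_equal(out, img)
    b = boxes[0]
    assert (b.x1, b.y1, b.x2, b.y2) == (60, 80, 100, 120)


def test_rotation_moves_boxes_with_content():
    img, box = _toy_image_and_box()
    out, boxes = sd.augment(img, [box], "random_rotate", seed=0, angle=35.0,
                            out_size=200)
    assert len(boxes) == 1
    ys, xs = np.where(out[:, :, 0] > 100)
    b = boxes[0]
    assert abs(xs.mean() - (b.x1 + b.x2) / 2) < 4
    assert abs(ys.mean() - (b.y1 + b.y2) / 2) < 4


def test_mean_blur_of_constant_image_is_identity():
    const = np.full((64, 64, 3), 137, np.uint8)
    out, _ = sd.augment(const, [], "mean_blur", seed=0, kernel=5, out_size=64)
    assert np.array_equal(out, const)


def test_blur_kernel_draws_are_odd_and_bounded():
    ks = set()
    img = np.zeros((16, 16, 3), np.uint8)
    for seed in range(300):
        rng = np.random.default_rng(seed)
        k = int(rng.choice(sd.BLUR_KERNELS))
        ks.add(k)
    assert ks == {5, 7, 9, 11, 13, 15}
    with pytest.raises(ValueError):
        sd.augment(img, [], "mean_blur", seed=0, kernel=4)


def test_crop_fractions_stay_within_bounds():
    """1000 sampled crops: empirical crop fraction within [0.40, 0.80]."""
    img = np.zeros((80, 80, 3), np.uint8)
    fracs = []
    for seed in range(1000):
        out_img, _ = sd.augment(img, [], "random_crop", seed=seed, out_size=80)
        rng = np.random.default_rng(seed)
        fracs.append(rng.uniform(*sd.CROP_RANGE))
    fracs = np.array(fracs)
    assert fracs.min() >= 0.40 and fracs.max() <= 0.80
    assert fracs.min() < 0.45 and fracs.max() > 0.75  # the range is exercised


def test_rotation_angles_stay_within_bounds():
    angles = np.array([np.random.default_rng(s).uniform(*sd.ROTATE_RANGE)
                       for s in range(1000)])
    assert angles.min() >= -60 and angles.max() <= 60
    assert angles.min() < -50 and angles.max() > 50


def test_augment_outputs_canonical_size():
    img, box = _toy_image_and_box()
    for op in sd.AUGMENT_OPS:
        out, boxes = sd.augment(img, [box], op, seed=1, out_size=640)
        assert out.shape == (640, 640, 3)
        for b in boxes:
            assert 0 <= b.x1 < b.x2 <= 640 and 0 <= b.y1 < b.y2 <= 640


def test_crop_drops_boxes_below_survival_floor():
    img = np.zeros((100, 100, 3), np.uint8)
    box = sd.LabeledBox(0, 0, 20, 20, 0)
    kept = dropped = 0
    for seed in range(40):
        out, boxes = sd.augment(img, [box], "random_crop", seed=seed, frac=0.5,
                                out_size=50)  # out 50 = crop size: no rescale
        if boxes:
            kept += 1
            assert boxes[0].area >= sd.BOX_SURVIVAL_FLOOR * box.area
        else:
            dropped += 1
    assert kept and dropped  # both outcomes occur across crop origins


def test_unknown_augmentation_rejected():
    img = np.zeros((32, 32, 3), np.uint8)
    with pytest.raises(ValueError, match="unknown augmentation"):
        sd.augment(img, [], "mosaic", seed=0)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def test_split_sizes_for_full_dataset():
    tr, va, te = sd.split_dataset(3251, sd.SplitSpec(seed=0))
    assert (len(tr), len(va), len(te)) == (2275, 325, 651)


@given(st.integers(3, 5000), st.integers(0, 2 ** 31 - 1))
@settings(max_examples=50, deadline=None)
def test_split_is_a_disjoint_partition(n, seed):
    tr, va, te = sd.split_dataset(n, sd.SplitSpec(seed=seed))
    assert len(tr) == int(np.floor(0.7 * n))
    assert len(va) == int(np.floor(0.1 * n))
    assert len(tr) + len(va) + len(te) == n
    assert sorted(np.concatenate([tr, va, te]).tolist()) == list(range(n))


def test_split_small_case_and_determinism():
    assert tuple(map(len, sd.split_dataset(10, sd.SplitSpec(seed=3)))) == (7, 1, 2)
    a = sd.split_dataset(100, sd.SplitSpec(seed=9))
    b = sd.split_dataset(100, sd.SplitSpec(seed=9))
    assert all(np.array_equal(x, y) for x, y in zip(a, b))


# ---------------------------------------------------------------------------
# annotation formats
# ---------------------------------------------------------------------------

def test_yolo_normalisation_line(tmp_path):
    img = np.zeros((640, 640, 3), np.uint8)
    s = sd.Sample(image=img, boxes=[sd.LabeledBox(0, 0, 320, 320, 3)])
    sd.write_dataset([s], "yolo_labels", tmp_path)
    line = (tmp_path / "labels" / "scene_00000.txt").read_text().strip()
    assert line == "3 0.250000 0.250000 0.500000 0.500000"


def test_coco_round_trip_preserves_boxes(tmp_path):
    rng = np.random.default_rng(0)
    samples = []
    for i in range(3):
        img = rng.integers(0, 255, (64, 64, 3)).astype(np.uint8)
        boxes = [sd.LabeledBox(4.5, 8.25, 30.0, 40.5, int(i % 5)),
                 sd.LabeledBox(10, 10, 20, 22, 4)]
        samples.append(sd.Sample(image=img, boxes=boxes, id=i))
    manifest = sd.write_dataset(samples, "coco_json", tmp_path)
    back = sd.read_coco(tmp_path)
    assert len(back) == 3
    for orig, rt in zip(samples, back):
        assert np.array_equal(orig.image, rt.image)
        for a, b in zip(orig.boxes, rt.boxes):
            assert np.allclose(a.as_array(), b.as_array(), atol=0.5)
            assert a.cls == b.cls
    # categories in the fixed class order
    import json
    coco = json.loads((tmp_path / "annotations.json").read_text())
    assert [c["name"] for c in coco["categories"]] == list(sd.CLASS_NAMES)


def test_yolo_round_trip_within_half_pixel(tmp_path):
    img = np.zeros((128, 128, 3), np.uint8)
    boxes = [sd.LabeledBox(3.2, 7.8, 100.4, 90.1, 2)]
    sd.write_dataset([sd.Sample(image=img, boxes=boxes)], "yolo_labels", tmp_path)
    back = sd.read_yolo(tmp_path)
    assert np.allclose(back[0].boxes[0].as_array(), boxes[0].as_array(), atol=0.5)


def test_manifest_histogram_matches_requested_composition(tmp_path):
    """A dataset assembled to a target per-class instance histogram is
    book-kept exactly in the manifest."""
    requested = {"unripe": 21, "half_ripe": 10, "ripe": 33,
                 "overripe": 18, "rotten": 13}
    rng = np.random.default_rng(1)
    pool = [cid for cid, name in enumerate(sd.CLASS_NAMES)
            for _ in range(requested[name])]
    rng.shuffle(pool)
    samples, i = [], 0
    img = np.zeros((32, 32, 3), np.uint8)
    while i < len(pool):
        take = int(rng.integers(1, 5))
        boxes = [sd.LabeledBox(1, 1, 10, 10, c) for c in pool[i:i + take]]
        samples.append(sd.Sample(image=img, boxes=boxes))
        i += take
    manifest = sd.write_dataset(samples, "coco_json", tmp_path)
    assert manifest["class_histogram"] == requested
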