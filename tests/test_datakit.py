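"""Dataset tooling: label I/O round trips and hand conversions, the five
augmentation operators, exact x5 expansion, stratified splitting, image
screening, and the synthetic scene generator."""

import numpy as np
import pytest
from PIL import Image

from yolosda import datakit as dk


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

def test_label_roundtrip(tmp_path):
    labels = [dk.BoxLabel(0, 0.5, 0.5, 0.2, 0.3),
              dk.BoxLabel(3, 0.25, 0.75, 0.1, 0.1),
              dk.BoxLabel(5, 0.9, 0.1, 0.05, 0.05)]
    path = tmp_path / "x.txt"
    dk.write_labels(labels, path)
    back = dk.read_labels(path)
    assert len(back) == 3
    for a, b in zip(labels, back):
        assert a.class_id == b.class_id
        for f in ("cx", "cy", "w", "h"):
            assert abs(getattr(a, f) - getattr(b, f)) < 1e-6


def test_pixel_box_normalisation_hand_computed():
    """Pixel box (100,150)-(300,350) on 640x640 -> the hand conversion."""
    lb = dk.BoxLabel.from_xyxy(2, 100, 150, 300, 350, 640, 640)
    assert (lb.cx, lb.cy, lb.w, lb.h) == (0.3125, 0.390625, 0.3125, 0.3125)


def test_out_of_range_class_rejected(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("7 0.5 0.5 0.1 0.1\n")
    with pytest.raises(ValueError, match=r"bad.txt:1.*class_id 7"):
        dk.read_labels(path)


def test_malformed_row_reported_with_line_number(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("0 0.5 0.5 0.1 0.1\n0 0.5 0.5\n")
    with pytest.raises(ValueError, match=r"bad.txt:2"):
        dk.read_labels(path)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@pytest.fixture()
def leaf_image(rng):
    return rng.integers(0, 255, size=(64, 64, 3)).astype(np.uint8)


def test_salt_pepper_density_zero_is_identity(leaf_image):
    labels = [dk.BoxLabel(0, 0.5, 0.5, 0.2, 0.2)]
    out, lbs = dk.augment(leaf_image, labels,
                          dk.AugmentOp("salt_pepper", {"density": 0.0}))
    np.testing.assert_array_equal(out, leaf_image)
    assert lbs == labels


def test_photometric_ops_leave_labels_unchanged(leaf_image):
    labels = [dk.BoxLabel(1, 0.4, 0.6, 0.3, 0.2)]
    for kind in ("gaussian_noise", "brightness", "exposure", "salt_pepper"):
        _, lbs = dk.augment(leaf_image, labels, dk.AugmentOp(kind, seed=4))
        assert lbs == labels


def test_full_turn_rotation_restores_labels(leaf_image):
    labels = [dk.BoxLabel(2, 0.3, 0.4, 0.2, 0.25)]
    _, lbs = dk.augment(leaf_image, labels,
                        dk.AugmentOp("rotation", {"angle": 360.0}))
    assert len(lbs) == 1
    for f in ("cx", "cy", "w", "h"):
        assert abs(getattr(lbs[0], f) - getattr(labels[0], f)) < 1e-6


def test_quarter_turn_rotation_corner_oracle():
    """+90 deg maps box (0.25, 0.25, 0.1, 0.2) to (0.75, 0.25, 0.2, 0.1),
    verified by rotating the four corners explicitly."""
    lb = dk.BoxLabel(0, 0.25, 0.25, 0.1, 0.2)
    out = dk.rotate_box(lb, 90.0, 640, 640)
    for got, want in zip((out.cx, out.cy, out.w, out.h),
                         (0.75, 0.25, 0.2, 0.1)):
        assert abs(got - want) < 1e-9
    # independent corner enumeration about the centre
    corners = [(0.2, 0.15), (0.3, 0.15), (0.3, 0.35), (0.2, 0.35)]
    rot = [(0.5 - (y - 0.5), 0.5 + (x - 0.5)) for x, y in corners]
    xs, ys = zip(*rot)
    assert abs((min(xs) + max(xs)) / 2 - out.cx) < 1e-9
    assert abs(max(ys) - min(ys) - out.h) < 1e-9


def test_rotation_image_and_box_stay_aligned():
    """A bright marker patch must remain inside its rotated box."""
    img = np.zeros((64, 64, 3), np.uint8)
    img[8:16, 40:48] = 255
    lb = dk.BoxLabel.from_xyxy(0, 40, 8, 48, 16, 64, 64)
    out, lbs = dk.augment(img, [lb], dk.AugmentOp("rotation",
                                                  {"angle": 90.0}))
    assert len(lbs) == 1
    x1, y1, x2, y2 = (int(round(v)) for v in lbs[0].to_xyxy(64, 64))
    inside = out[max(y1, 0):y2, max(x1, 0):x2].sum()
    assert inside > 0.8 * out.sum()


def test_rotated_boxes_stay_inside_unit_square(rng):
    for _ in range(25):
        lb = dk.BoxLabel(0, rng.uniform(0.2, 0.8), rng.uniform(0.2, 0.8),
                         rng.uniform(0.05, 0.4), rng.uniform(0.05, 0.4))
        out = dk.rotate_box(lb, float(rng.uniform(-180, 180)), 640, 640)
        if out is None:
            continue
        assert 0 <= out.cx - out.w / 2 and out.cx + out.w / 2 <= 1 + 1e-9
        assert 0 <= out.cy - out.h / 2 and out.cy + out.h / 2 <= 1 + 1e-9
        assert out.w > 0 and out.h > 0


def test_unknown_augment_kind_rejected():
    with pytest.raises(ValueError, match="unknown augmentation"):
        dk.AugmentOp("cutmix")


# ---------------------------------------------------------------------------
# expansion and splitting
# ---------------------------------------------------------------------------

def _make_tiny_dataset(root, counts, size=12):
    rng = np.random.default_rng(0)
    items = []
    for cid, n in enumerate(counts):
        for i in range(n):
            stem = root / f"c{cid}_{i:04d}"
            img = rng.integers(0, 255, (size, size, 3)).astype(np.uint8)
            Image.fromarray(img).save(f"{stem}.png")
            dk.write_labels([dk.BoxLabel(cid, 0.5, 0.5, 0.4, 0.4)],
                            f"{stem}.txt")
            items.append(dk.ManifestItem(f"{stem}.png", f"{stem}.txt", cid))
    return dk.DatasetManifest(items, dk.CLASS_NAMES, str(root))


def test_expand_by_five_keeps_original_plus_four_copies(tmp_path):
    man = _make_tiny_dataset(tmp_path, (3, 2, 1, 1, 2, 3))
    out = dk.expand_dataset(man, factor=5, seed=0,
                            out_dir=str(tmp_path / "aug"))
    assert len(out) == 5 * len(man)
    before, after = man.per_class_counts(), out.per_class_counts()
    assert all(after[c] == 5 * before[c] for c in before)
    ops = {it.provenance for it in out.items if it.provenance != "original"}
    assert ops <= {f"augmented({k})" for k in dk.AUGMENT_KINDS}
    n_orig = sum(it.provenance == "original" for it in out.items)
    assert n_orig == len(man)


def test_expand_factor_one_is_identity(tmp_path):
    man = _make_tiny_dataset(tmp_path, (2, 1, 0, 0, 0, 0))
    out = dk.expand_dataset(man, factor=1, seed=0)
    assert [it.image for it in out.items] == [it.image for it in man.items]


def test_split_exact_ratios_on_ten_items(tmp_path):
    items = [dk.ManifestItem(f"i{k}.png", f"i{k}.txt", 0) for k in range(10)]
    man = dk.DatasetManifest(items, dk.CLASS_NAMES, ".")
    out = dk.split_dataset(man, (7, 2, 1), seed=0)
    sizes = {s: len(out.subset(s)) for s in ("train", "val", "test")}
    assert sizes == {"train": 7, "val": 2, "test": 1}


def test_split_7360_largest_remainder():
    """7:2:1 of 7360 under largest-remainder rounding is 5152/1472/736."""
    counts = (1280, 1245, 1215, 1195, 1180, 1245)
    items = [dk.ManifestItem(f"c{c}_{k}.png", "", c)
             for c, n in enumerate(counts) for k in range(n)]
    out = dk.split_dataset(dk.DatasetManifest(items, dk.CLASS_NAMES, "."),
                           (7, 2, 1), seed=1)
    sizes = {s: len(out.subset(s)) for s in ("train", "val", "test")}
    assert sizes == {"train": 5152, "val": 1472, "test": 736}


def test_split_is_deterministic_and_disjoint():
    items = [dk.ManifestItem(f"i{k}.png", "", k % 6) for k in range(101)]
    man = dk.DatasetManifest(items, dk.CLASS_NAMES, ".")
    a = dk.split_dataset(man, (7, 2, 1), seed=9)
    b = dk.split_dataset(man, (7, 2, 1), seed=9)
    key = lambda m: sorted((it.image, it.split) for it in m.items)
    assert key(a) == key(b)
    names = [it.image for it in a.items]
    assert sorted(names) == sorted(it.image for it in man.items)
    splits = {}
    for it in a.items:
        splits.setdefault(it.split, set()).add(it.image)
    assert sum(len(v) for v in splits.values()) == len(set(names))


def test_split_rejects_nonpositive_ratios():
    man = dk.DatasetManifest([], dk.CLASS_NAMES, ".")
    with pytest.raises(ValueError, match="positive"):
        dk.split_dataset(man, (7, 0, 1))


# ---------------------------------------------------------------------------
# image screening
# ---------------------------------------------------------------------------

def test_filter_rules(tmp_path, rng):
    big = rng.integers(0, 255, (220, 220, 3)).astype(np.uint8)
    Image.fromarray(big).save(tmp_path / "ok.png")
    Image.fromarray(big).save(tmp_path / "dup.png")
    Image.fromarray(big[:100, :100]).save(tmp_path / "small.png")
    Image.fromarray(big[..., 0]).convert("L").save(tmp_path / "grey.png")
    rep = dk.filter_images([str(tmp_path / n) for n in
                            ("ok.png", "dup.png", "small.png", "grey.png")],
                           min_size=200)
    assert rep["kept"] == [str(tmp_path / "ok.png")]
    reasons = dict(rep["rejected"])
    assert "duplicate" in reasons[str(tmp_path / "dup.png")]
    assert "too small" in reasons[str(tmp_path / "small.png")]
    assert "non-RGB" in reasons[str(tmp_path / "grey.png")]


# ---------------------------------------------------------------------------
# synthetic scenes
# ---------------------------------------------------------------------------

def test_scene_zero_objects_empty_labels():
    img, labels = dk.generate_scene(seed=1, n_objects=0, size=64)
    assert img.shape == (64, 64, 3) and labels == []


def test_scene_boxes_count_and_bounds():
    _, labels = dk.generate_scene(seed=2, n_objects=5, size=128)
    assert len(labels) == 5
    for lb in labels:
        lb.validate()
        assert 0 <= lb.cx - lb.w / 2 and lb.cx + lb.w / 2 <= 1


def test_scene_seed_reproducibility():
    a_img, a_lb = dk.generate_scene(seed=11, n_objects=4, size=96)
    b_img, b_lb = dk.generate_scene(seed=11, n_objects=4, size=96)
    np.testing.assert_array_equal(a_img, b_img)
    assert a_lb == b_lb
    c_img, _ = dk.generate_scene(seed=12, n_objects=4, size=96)
    assert (a_img != c_img).any()


def test_scene_class_mix_restricts_classes():
    _, labels = dk.generate_scene(seed=3, n_objects=6, size=96,
                                  class_mix=[0, 0, 1, 0, 0, 0])
    assert {lb.class_id for lb in labels} == {2}


def test_write_and_load_dataset_roundtrip(tmp_path):
    man = dk.write_dataset(str(tmp_path / "d"), 6, seed=0, size=64)
    back = dk.load_manifest(str(tmp_path / "d"))
    assert len(back) == len(man) == 6
    assert {it.split for it in back.items} <= {"train", "val", "test"}
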