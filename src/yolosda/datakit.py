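"""Dataset tooling: YOLO-format labels, augmentation, expansion, splitting,
image filtering, and a synthetic leaf-scene generator.

The augmentation protocol mirrors a field-image collection workflow for
peanut foliar disease: five operators (random rotation, Gaussian noise,
salt-and-pepper noise, brightness adjustment, exposure adjustment) expand
every class five-fold — each original is kept and four augmented copies are
added, the operators drawn without replacement. The expanded set is split
7:2:1 into train/val/test, stratified by class, with largest-remainder
rounding.

Because no public accession of the original field imagery exists, the
synthetic generator emulates its structure: leaf-shaped objects with
class-conditional lesion patterns (spot density, colour, chlorosis) on a
cluttered soil/foliage background, with exact bounding-box labels.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
from PIL import Image

CLASS_NAMES = (
    "healthy",
    "early_leaf_spot",
    "late_leaf_spot",
    "early_rust",
    "late_rust",
    "nutrient_deficiency",
)

AUGMENT_KINDS = ("rotation", "gaussian_noise", "salt_pepper",
                 "brightness", "exposure")


# ---------------------------------------------------------------------------
# labels
# ---------------------------------------------------------------------------

@dataclass
class BoxLabel:
    """One normalized ground-truth box: class id + (cx, cy, w, h) in [0,1]."""

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def validate(self, num_classes: int = len(CLASS_NAMES)):
        errs = []
        if not 0 <= self.class_id < num_classes:
            errs.append(f"class_id {self.class_id} outside [0, {num_classes})")
        for name in ("cx", "cy", "w", "h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errs.append(f"{name}={v} outside [0, 1]")
        if self.w <= 0 or self.h <= 0:
            errs.append(f"degenerate box w={self.w} h={self.h}")
        if errs:
            raise ValueError("; ".join(errs))
        return self

    def to_xyxy(self, width: int, height: int) -> tuple:
        return ((self.cx - self.w / 2) * width, (self.cy - self.h / 2) * height,
                (self.cx + self.w / 2) * width, (self.cy + self.h / 2) * height)

    @classmethod
    def from_xyxy(cls, class_id, x1, y1, x2, y2, width, height) -> "BoxLabel":
        return cls(class_id, (x1 + x2) / 2 / width, (y1 + y2) / 2 / height,
                   (x2 - x1) / width, (y2 - y1) / height)


def read_labels(path, num_classes: int = len(CLASS_NAMES)) -> list:
    """Parse a whitespace-delimited 'class cx cy w h' label file."""
    labels, errors = [], []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            try:
                if len(parts) != 5:
                    raise ValueError(f"expected 5 fields, got {len(parts)}")
                lb = BoxLabel(int(parts[0]), *map(float, parts[1:]))
                lb.validate(num_classes)
                labels.append(lb)
            except ValueError as e:
                errors.append(f"{path}:{lineno}: {e}")
    if errors:
        raise ValueError("malformed label rows:\n" + "\n".join(errors))
    return labels


def write_labels(labels, path):
    with open(path, "w") as f:
        for lb in labels:
            f.write(f"{lb.class_id} {lb.cx:.6f} {lb.cy:.6f} "
                    f"{lb.w:.6f} {lb.h:.6f}\n")


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentOp:
    """One augmentation operator application."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.kind not in AUGMENT_KINDS:
            raise ValueError(f"unknown augmentation {self.kind!r}; "
                             f"choose from {AUGMENT_KINDS}")


DEFAULT_PARAMS = {
    "rotation": {"angle": None},          # None -> uniform in [-180, 180)
    "gaussian_noise": {"sigma": 10.0},    # grey levels
    "salt_pepper": {"density": 0.02},
    "brightness": {"delta": None},        # None -> uniform in [-0.25, 0.25]
    "exposure": {"gamma": None},          # None -> uniform in [0.7, 1.4]
}


def rotate_box(label: BoxLabel, angle_deg: float, width: int, height: int,
               min_area_frac: float = 0.1):
    """Axis-aligned hull of the four rotated corners, clipped to the image.

    Rotation is about the image centre; +90 degrees maps a point (x, y) to
    (W - y, x) (the convention under which the paired image rotation below
    moves pixels identically). Returns None when the clipped box keeps less
    than ``min_area_frac`` of its original area.
    """
    t = np.deg2rad(angle_deg)
    c, s = np.cos(t), np.sin(t)
    cx0, cy0 = width / 2.0, height / 2.0
    x1, y1, x2, y2 = label.to_xyxy(width, height)
    corners = np.array([[x1, y1], [x2, y1], [x2, y2], [x1, y2]])
    rel = corners - (cx0, cy0)
    rot = np.stack([c * rel[:, 0] - s * rel[:, 1],
                    s * rel[:, 0] + c * rel[:, 1]], axis=1) + (cx0, cy0)
    nx1, ny1 = rot.min(axis=0)
    nx2, ny2 = rot.max(axis=0)
    cx1, cy1 = max(nx1, 0.0), max(ny1, 0.0)
    cx2, cy2 = min(nx2, width), min(ny2, height)
    if cx2 <= cx1 or cy2 <= cy1:
        return None
    orig_area = (x2 - x1) * (y2 - y1)
    if (cx2 - cx1) * (cy2 - cy1) < min_area_frac * orig_area:
        return None
    return BoxLabel.from_xyxy(label.class_id, cx1, cy1, cx2, cy2,
                              width, height)


def _rotate_image(img: np.ndarray, angle_deg: float) -> np.ndarray:
    from scipy import ndimage
    # ndimage rotates rows->cols for positive angles; negate so that a
    # positive angle matches the (x, y) -> (-y, x) corner convention above
    out = ndimage.rotate(img.astype(np.float32), -angle_deg, axes=(0, 1),
                         reshape=False, order=1, mode="nearest")
    return np.clip(out, 0, 255).astype(np.uint8)


def augment(image: np.ndarray, labels: list, op: AugmentOp):
    """Apply one operator; photometric ops leave the labels untouched."""
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    rng = np.random.default_rng(op.seed)
    p = {**DEFAULT_PARAMS[op.kind], **op.params}
    H, W = image.shape[:2]
    if op.kind == "rotation":
        angle = p["angle"]
        if angle is None:
            angle = float(rng.uniform(-180.0, 180.0))
        out = _rotate_image(image, angle)
        new_labels = [rotate_box(lb, angle, W, H) for lb in labels]
        return out, [lb for lb in new_labels if lb is not None]
    if op.kind == "gaussian_noise":
        noise = rng.normal(0.0, p["sigma"], image.shape)
        out = np.clip(image.astype(np.float32) + noise, 0, 255)
        return out.astype(np.uint8), list(labels)
    if op.kind == "salt_pepper":
        out = image.copy()
        d = p["density"]
        if d > 0:
            mask = rng.random((H, W))
            out[mask < d / 2] = 0
            out[(mask >= d / 2) & (mask < d)] = 255
        return out, list(labels)
    if op.kind == "brightness":
        delta = p["delta"]
        if delta is None:
            delta = float(rng.uniform(-0.25, 0.25))
        out = np.clip(image.astype(np.float32) * (1.0 + delta), 0, 255)
        return out.astype(np.uint8), list(labels)
    # exposure (gamma)
    gamma = p["gamma"]
    if gamma is None:
        gamma = float(rng.uniform(0.7, 1.4))
    out = 255.0 * (image.astype(np.float32) / 255.0) ** gamma
    return np.clip(out, 0, 255).astype(np.uint8), list(labels)


# ---------------------------------------------------------------------------
# manifests, expansion, splitting
# ---------------------------------------------------------------------------

@dataclass
class ManifestItem:
    image: str
    label: str
    category: int           # image-level disease category
    split: str = ""         # "", "train", "val" or "test"
    provenance: str = "original"  # or "augmented(<op>)"


@dataclass
class DatasetManifest:
    items: list
    class_names: tuple = CLASS_NAMES
    root: str = "."

    def __len__(self):
        return len(self.items)

    def per_class_counts(self) -> dict:
        counts = {i: 0 for i in range(len(self.class_names))}
        for it in self.items:
            counts[it.category] += 1
        return counts

    def subset(self, split: str) -> "DatasetManifest":
        return DatasetManifest([it for it in self.items if it.split == split],
                               self.class_names, self.root)


def expand_dataset(manifest: DatasetManifest, factor: int = 5,
                   seed: int = 0, out_dir: str | None = None,
                   keep_original: bool = True) -> DatasetManifest:
    """Five-fold expansion: every image keeps its original plus
    ``factor - 1`` augmented copies, operators sampled without replacement.

    Per-class counts scale exactly by ``factor``. With ``keep_original``
    False, ``factor`` augmented copies are written instead (x(factor+1)
    total).
    """
    if factor < 1:
        raise ValueError("expansion factor must be >= 1")
    n_copies = factor - 1 if keep_original else factor
    if n_copies > len(AUGMENT_KINDS):
        raise ValueError(f"cannot draw {n_copies} distinct operators from "
                         f"{len(AUGMENT_KINDS)}")
    rng = np.random.default_rng(seed)
    out_dir = out_dir or manifest.root
    os.makedirs(out_dir, exist_ok=True)
    new_items = []
    for it in manifest.items:
        if keep_original:
            new_items.append(it)
        if n_copies == 0:
            continue
        image = np.asarray(Image.open(it.image).convert("RGB"))
        labels = read_labels(it.label, len(manifest.class_names))
        kinds = rng.choice(len(AUGMENT_KINDS), size=n_copies, replace=False)
        stem = os.path.splitext(os.path.basename(it.image))[0]
        for k in kinds:
            kind = AUGMENT_KINDS[k]
            op = AugmentOp(kind, seed=int(rng.integers(2 ** 31)))
            aug_img, aug_labels = augment(image, labels, op)
            ipath = os.path.join(out_dir, f"{stem}_{kind}.png")
            lpath = os.path.join(out_dir, f"{stem}_{kind}.txt")
            Image.fromarray(aug_img).save(ipath)
            write_labels(aug_labels, lpath)
            new_items.append(ManifestItem(ipath, lpath, it.category,
                                          it.split, f"augmented({kind})"))
    return DatasetManifest(new_items, manifest.class_names, out_dir)


def _largest_remainder(n: int, ratios) -> list:
    ratios = np.asarray(ratios, dtype=np.float64)
    quota = n * ratios / ratios.sum()
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    order = np.argsort(-(quota - base), kind="stable")
    for i in order[:rem]:
        base[i] += 1
    return base.tolist()


def split_dataset(manifest: DatasetManifest, ratios=(7, 2, 1),
                  seed: int = 0) -> DatasetManifest:
    """Stratified train/val/test partition with largest-remainder rounding.

    Split totals follow largest-remainder rounding of the whole manifest
    (7360 at 7:2:1 gives exactly 5152/1472/736); within that budget every
    class receives its proportional floor and the leftover items go to the
    (class, split) pairs with the largest fractional remainders. Items are
    shuffled per class with the seed, so the partition is reproducible.
    """
    if any(r <= 0 for r in ratios):
        raise ValueError("split ratios must be positive")
    rng = np.random.default_rng(seed)
    names = ("train", "val", "test")[:len(ratios)]
    rtot = float(sum(ratios))
    cids = sorted({it.category for it in manifest.items})
    by_class = {c: [it for it in manifest.items if it.category == c]
                for c in cids}
    totals = _largest_remainder(len(manifest.items), ratios)
    sizes = {c: [int(len(by_class[c]) * r / rtot) for r in ratios]
             for c in cids}
    deficits = [t - sum(sizes[c][s] for c in cids)
                for s, t in enumerate(totals)]
    remainders = {c: len(by_class[c]) - sum(sizes[c]) for c in cids}
    fracs = sorted(((len(by_class[c]) * r / rtot) % 1.0, c, s)
                   for c in cids for s, r in enumerate(ratios))
    for _, c, s in reversed(fracs):
        if remainders[c] > 0 and deficits[s] > 0:
            sizes[c][s] += 1
            remainders[c] -= 1
            deficits[s] -= 1

    items = []
    for cid in cids:
        cls_items = by_class[cid]
        order = rng.permutation(len(cls_items))
        bounds = np.cumsum([0] + sizes[cid])
        for si, name in enumerate(names):
            for j in order[bounds[si]:bounds[si + 1]]:
                items.append(replace(cls_items[j], split=name))
    return DatasetManifest(items, manifest.class_names, manifest.root)


# ---------------------------------------------------------------------------
# image filtering
# ---------------------------------------------------------------------------

def average_hash(img: Image.Image, hash_size: int = 8) -> np.ndarray:
    g = np.asarray(img.convert("L").resize((hash_size, hash_size),
                                           Image.BILINEAR), dtype=np.float32)
    return (g > g.mean()).ravel()


def filter_images(paths, min_size: int = 200,
                  duplicate_distance: int = 5) -> dict:
    """Screening rules for collected imagery: reject non-RGB files, images
    below ``min_size`` in either dimension, and perceptual-hash duplicates
    (Hamming distance <= ``duplicate_distance`` on an 8x8 average hash).

    Returns {"kept": [...], "rejected": [(path, reason), ...]}.
    """
    kept, rejected, hashes = [], [], []
    for path in paths:
        try:
            img = Image.open(path)
            img.load()
        except Exception as e:  # unreadable file
            rejected.append((path, f"unreadable: {e}"))
            continue
        if img.mode != "RGB":
            rejected.append((path, f"non-RGB mode {img.mode}"))
            continue
        if min(img.size) < min_size:
            rejected.append((path, f"too small {img.size[0]}x{img.size[1]}"))
            continue
        h = average_hash(img)
        dup = next((p for p, h0 in hashes
                    if int((h != h0).sum()) <= duplicate_distance), None)
        if dup is not None:
            rejected.append((path, f"duplicate of {dup}"))
            continue
        hashes.append((path, h))
        kept.append(path)
    return {"kept": kept, "rejected": rejected}


# ---------------------------------------------------------------------------
# synthetic leaf scenes
# ---------------------------------------------------------------------------

def _smooth_noise(rng, size, cells, lo, hi):
    """Low-frequency noise field upsampled bilinearly to size x size."""
    from scipy import ndimage
    base = rng.uniform(lo, hi, (cells, cells))
    return ndimage.zoom(base, size / cells, order=1)[:size, :size]


_LESION_STYLE = {
    # class id -> (n spots range, radius range, colour, chlorosis strength)
    0: ((0, 0), (0, 0), None, 0.0),
    1: ((3, 7), (2, 5), (96, 64, 32), 0.0),
    2: ((9, 16), (4, 8), (56, 40, 24), 0.1),
    3: ((4, 9), (2, 5), (200, 120, 40), 0.0),
    4: ((12, 21), (3, 7), (190, 90, 30), 0.25),
    5: ((0, 0), (0, 0), None, 0.7),
}


def generate_scene(seed: int, n_objects: int = 5, class_mix=None,
                   size: int = 640):
    """One synthetic field scene: leaves with class-conditional lesions on a
    cluttered background, plus exact box labels.

    ``class_mix`` optionally weights the 6 classes; by default classes are
    drawn uniformly. Deterministic in ``seed``.
    """
    if n_objects < 0:
        raise ValueError("n_objects must be >= 0")
    rng = np.random.default_rng(seed)
    nclass = len(CLASS_NAMES)
    probs = (np.full(nclass, 1 / nclass) if class_mix is None
             else np.asarray(class_mix, float) / np.sum(class_mix))

    # soil/foliage background with low-frequency clutter
    img = np.zeros((size, size, 3), dtype=np.float32)
    img[..., 0] = _smooth_noise(rng, size, 8, 70, 120)
    img[..., 1] = _smooth_noise(rng, size, 8, 55, 100)
    img[..., 2] = _smooth_noise(rng, size, 8, 30, 60)
    img += rng.normal(0, 6, img.shape)

    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    labels = []
    for _ in range(n_objects):
        cid = int(rng.choice(nclass, p=probs))
        a = rng.uniform(0.055, 0.14) * size   # semi-axes in pixels
        b = a * rng.uniform(0.45, 0.8)
        theta = rng.uniform(0, np.pi)
        cx = rng.uniform(a, size - a)
        cy = rng.uniform(a, size - a)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0

        green = np.array([rng.uniform(40, 70), rng.uniform(110, 160),
                          rng.uniform(35, 70)], dtype=np.float32)
        spots_rng, radius_rng, colour, chlorosis = _LESION_STYLE[cid]
        if chlorosis > 0:  # yellowing toward (200, 190, 60)
            grad = np.clip((u / a + 1) / 2, 0, 1)[..., None] * chlorosis
            leaf = green[None, None, :] * (1 - grad) + \
                np.array([205, 185, 60], np.float32) * grad
        else:
            leaf = np.broadcast_to(green, (size, size, 3)).copy()
        shade = 1.0 - 0.25 * np.clip((v / max(b, 1e-6) + 1) / 2, 0, 1)
        img[mask] = (leaf * shade[..., None])[mask]

        n_spots = int(rng.integers(*spots_rng)) if spots_rng[1] > 0 else 0
        for _s in range(n_spots):
            su = rng.uniform(-0.75, 0.75) * a
            sv = rng.uniform(-0.75, 0.75) * b
            sx = cx + su * ct - sv * st
            sy = cy + su * st + sv * ct
            r = rng.uniform(*radius_rng)
            spot = ((xx - sx) ** 2 + (yy - sy) ** 2 <= r * r) & mask
            jitter = rng.uniform(0.8, 1.2)
            img[spot] = np.array(colour, np.float32) * jitter

        ys, xs = np.nonzero(mask)
        if len(xs) == 0:
            continue
        labels.append(BoxLabel.from_xyxy(
            cid, max(xs.min() - 1, 0), max(ys.min() - 1, 0),
            min(xs.max() + 2, size), min(ys.max() + 2, size), size, size))

    return np.clip(img, 0, 255).astype(np.uint8), labels


def write_dataset(root: str, n_scenes: int, seed: int = 0, size: int = 640,
                  n_objects=(2, 6), splits=(7, 2, 1)) -> DatasetManifest:
    """Generate, save and split a synthetic dataset under ``root``.

    Layout: images/<split>/*.png with parallel labels/<split>/*.txt and a
    dataset.yaml descriptor.
    """
    import yaml
    rng = np.random.default_rng(seed)
    tmp_items = []
    os.makedirs(root, exist_ok=True)
    scenes = []
    for i in range(n_scenes):
        n = int(rng.integers(n_objects[0], n_objects[1] + 1))
        img, labels = generate_scene(int(rng.integers(2 ** 31)), n, size=size)
        category = labels[0].class_id if labels else 0
        scenes.append((img, labels, category))
        tmp_items.append(ManifestItem(f"scene_{i:05d}", "", category))
    manifest = split_dataset(
        DatasetManifest(tmp_items, CLASS_NAMES, root), splits, seed)
    final_items = []
    for it in manifest.items:
        idx = int(it.image.split("_")[1])
        img, labels, category = scenes[idx]
        idir = os.path.join(root, "images", it.split)
        ldir = os.path.join(root, "labels", it.split)
        os.makedirs(idir, exist_ok=True)
        os.makedirs(ldir, exist_ok=True)
        ipath = os.path.join(idir, f"{it.image}.png")
        lpath = os.path.join(ldir, f"{it.image}.txt")
        Image.fromarray(img).save(ipath)
        write_labels(labels, lpath)
        final_items.append(ManifestItem(ipath, lpath, category, it.split))
    manifest = DatasetManifest(final_items, CLASS_NAMES, root)
    with open(os.path.join(root, "dataset.yaml"), "w") as f:
        yaml.safe_dump({"path": root, "names": list(CLASS_NAMES),
                        "images": "images", "labels": "labels"}, f)
    return manifest


def load_manifest(root: str) -> DatasetManifest:
    """Rebuild a manifest from an images/labels directory layout."""
    items = []
    for split in ("train", "val", "test"):
        idir = os.path.join(root, "images", split)
        if not os.path.isdir(idir):
            continue
        for name in sorted(os.listdir(idir)):
            stem = os.path.splitext(name)[0]
            lpath = os.path.join(root, "labels", split, stem + ".txt")
            labels = read_labels(lpath) if os.path.exists(lpath) else []
            category = labels[0].class_id if labels else 0
            items.append(ManifestItem(os.path.join(idir, name), lpath,
                                      category, split))
    return DatasetManifest(items, CLASS_NAMES, root)
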