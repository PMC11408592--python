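"""Dataset scanning, stratified splitting, augmentation, synthetic images.

The on-disk layout is folder-per-class: ``root/<Class>/*.{jpg,jpeg,png}``
with classes Cyst, Normal, Stone, Tumor (alphabetical order is canonical
everywhere: manifests, label indices, confusion matrices).

"Doubling by augmentation" is realized logically: a loader built with
``duplication=k`` exposes ``k * n`` indices, and every logical copy passes
independently through the stochastic transform pipeline.  Nothing is
duplicated on disk.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image, ImageEnhance
from scipy.ndimage import gaussian_filter

CLASSES = ("Cyst", "Normal", "Stone", "Tumor")

#: per-class composition of the CT kidney study dataset (12,446 images)
PAPER_CLASS_COUNTS = {"Cyst": 3709, "Normal": 5077, "Stone": 1377, "Tumor": 2283}

#: the study's train/validation proportion (9,725 of 12,446 for training)
PAPER_TRAIN_FRACTION = 9725 / 12446

IMAGENET_MEAN = (0.485, 0.456, 0.406)
IMAGENET_STD = (0.229, 0.224, 0.225)

_IMAGE_EXTS = {".jpg", ".jpeg", ".png"}


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass
class DatasetManifest:
    """Immutable listing of (path, label) records plus per-class counts."""

    records: list[tuple[str, str]]
    class_counts: dict[str, int]
    root: str

    def __post_init__(self):
        labels = {lab for _, lab in self.records}
        unknown = labels - set(self.class_counts)
        if unknown:
            raise ValueError(f"records carry labels outside the class set: {unknown}")
        if sum(self.class_counts.values()) != len(self.records):
            raise ValueError("class_counts do not sum to the number of records")
        paths = [p for p, _ in self.records]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest contains duplicate paths")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def classes(self) -> tuple[str, ...]:
        return tuple(self.class_counts.keys())

    @classmethod
    def from_records(cls, records, root="", classes=CLASSES) -> "DatasetManifest":
        counts = {c: 0 for c in classes}
        for _, lab in records:
            if lab not in counts:
                raise ValueError(f"label {lab!r} not in configured classes {classes}")
            counts[lab] += 1
        return cls(list(records), counts, str(root))

    def subset(self, indices) -> "DatasetManifest":
        recs = [self.records[i] for i in indices]
        return DatasetManifest.from_records(recs, self.root, self.classes)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.records, columns=["path", "label"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, root="", classes=CLASSES) -> "DatasetManifest":
        df = pd.read_csv(path)
        return cls.from_records(list(zip(df["path"], df["label"])), root, classes)


def scan_image_folder(root, classes=CLASSES) -> DatasetManifest:
    """Enumerate JPEG/PNG files under one folder per class, sorted."""
    root = Path(root)
    missing = [c for c in classes if not (root / c).is_dir()]
    if missing:
        raise FileNotFoundError(
            f"missing class folder(s) {missing} under {root}; expected one "
            f"subdirectory per class: {list(classes)}"
        )
    records = []
    for c in classes:
        for p in sorted((root / c).iterdir()):
            if p.suffix.lower() in _IMAGE_EXTS and p.is_file():
                records.append((str(p), c))
    if not records:
        raise ValueError(f"no images found under {root}")
    return DatasetManifest.from_records(records, str(root), classes)


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    train_fraction: float = PAPER_TRAIN_FRACTION
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly inside (0, 1)")


def split(manifest: DatasetManifest, spec: SplitSpec):
    """Stratified train/validation split with largest-remainder rounding.

    The total training size is ``round(f * n)``; per-class allocations take
    ``floor(f * n_c)`` and the leftover goes to the classes with the largest
    fractional remainders (ties broken by class order), so totals are exact.
    Returns ``(train_manifest, val_manifest)``; reproducible under ``seed``.
    """
    n = len(manifest)
    f = spec.train_fraction
    n_train = int(round(f * n))
    if n_train == 0 or n_train == n:
        raise ValueError(
            f"train_fraction={f} yields an empty split on {n} records"
        )
    classes = manifest.classes
    for c in classes:
        if manifest.class_counts[c] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 records")
    rng = np.random.default_rng(spec.seed)
    by_class = {c: [] for c in classes}
    for i, (_, lab) in enumerate(manifest.records):
        by_class[lab].append(i)

    if spec.stratified:
        quotas = {c: f * manifest.class_counts[c] for c in classes}
        alloc = {c: math.floor(quotas[c]) for c in classes}
        leftover = n_train - sum(alloc.values())
        order = sorted(
            range(len(classes)),
            key=lambda i: (-(quotas[classes[i]] - alloc[classes[i]]), i),
        )
        for i in order[:leftover]:
            alloc[classes[i]] += 1
        train_idx = []
        for c in classes:
            idx = np.array(by_class[c])
            rng.shuffle(idx)
            train_idx.extend(idx[: alloc[c]].tolist())
    else:
        idx = np.arange(n)
        rng.shuffle(idx)
        train_idx = idx[:n_train].tolist()

    train_set = set(train_idx)
    val_idx = [i for i in range(n) if i not in train_set]
    return manifest.subset(sorted(train_idx)), manifest.subset(val_idx)


def augmented_size(n: int, factor: int) -> int:
    """Logical dataset size after x``factor`` augmentation duplication."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if int(factor) != factor or factor < 1:
        raise ValueError("duplication factor must be a positive integer")
    return int(n) * int(factor)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationConfig:
    """The training transform stack: flips, color jitter, resize, center
    crop, ImageNet standardization and random erasing.  Evaluation mode
    applies only resize -> center crop -> normalize."""

    random_horizontal_flip: float = 0.5
    random_vertical_flip: float = 0.5
    color_jitter: tuple[float, float, float, float] = (0.1, 0.1, 0.1, 0.02)
    resize_to: tuple[int, int] = (256, 256)
    center_crop: tuple[int, int] = (224, 224)
    normalize_mean: tuple[float, float, float] = IMAGENET_MEAN
    normalize_std: tuple[float, float, float] = IMAGENET_STD
    random_erasing_p: float = 0.1
    duplication_factor: int = 2

    def __post_init__(self):
        for p in (self.random_horizontal_flip, self.random_vertical_flip,
                  self.random_erasing_p):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if (self.center_crop[0] > self.resize_to[0]
                or self.center_crop[1] > self.resize_to[1]):
            raise ValueError("center_crop must not exceed resize_to")
        if self.duplication_factor < 1:
            raise ValueError("duplication_factor must be >= 1")


def _load_image(image):
    if isinstance(image, (str, os.PathLike)):
        path = str(image)
        try:
            with Image.open(path) as im:
                return im.convert("RGB")
        except Exception as exc:
            raise ValueError(f"cannot decode image {path!r}: {exc}") from exc
    if isinstance(image, np.ndarray):
        return Image.fromarray(image).convert("RGB")
    return image.convert("RGB")


def apply_transforms(image, cfg: AugmentationConfig = AugmentationConfig(),
                     seed=0, training: bool = True) -> np.ndarray:
    """Transform one decoded 8-bit image into a standardized [3, H, W] array.

    Deterministic under a fixed ``seed`` (an int or ``SeedSequence``).
    Grayscale inputs are replicated to three channels.
    """
    img = _load_image(image)
    rng = np.random.default_rng(seed)
    if training:
        if rng.random() < cfg.random_horizontal_flip:
            img = img.transpose(Image.FLIP_LEFT_RIGHT)
        if rng.random() < cfg.random_vertical_flip:
            img = img.transpose(Image.FLIP_TOP_BOTTOM)
        b, c, s, h = cfg.color_jitter
        if b > 0:
            img = ImageEnhance.Brightness(img).enhance(rng.uniform(1 - b, 1 + b))
        if c > 0:
            img = ImageEnhance.Contrast(img).enhance(rng.uniform(1 - c, 1 + c))
        if s > 0:
            img = ImageEnhance.Color(img).enhance(rng.uniform(1 - s, 1 + s))
        if h > 0:
            shift = int(round(rng.uniform(-h, h) * 255))
            if shift:
                hsv = np.array(img.convert("HSV"))
                hsv[..., 0] = (hsv[..., 0].astype(np.int16) + shift) % 256
                img = Image.fromarray(hsv, "HSV").convert("RGB")
    img = img.resize(cfg.resize_to, Image.BILINEAR)
    w, hgt = img.size
    cw, ch = cfg.center_crop[1], cfg.center_crop[0]
    left, top = (w - cw) // 2, (hgt - ch) // 2
    img = img.crop((left, top, left + cw, top + ch))
    arr = np.asarray(img, dtype=np.float32) / 255.0
    arr = np.moveaxis(arr, -1, 0)  # [3, H, W]
    mean = np.asarray(cfg.normalize_mean, np.float32)[:, None, None]
    std = np.asarray(cfg.normalize_std, np.float32)[:, None, None]
    arr = (arr - mean) / std
    if training and cfg.random_erasing_p > 0 and rng.random() < cfg.random_erasing_p:
        H, W = arr.shape[1:]
        area = rng.uniform(0.02, 0.33) * H * W
        aspect = math.exp(rng.uniform(math.log(0.3), math.log(3.3)))
        eh = min(H, max(1, int(round(math.sqrt(area * aspect)))))
        ew = min(W, max(1, int(round(math.sqrt(area / aspect)))))
        top = int(rng.integers(0, H - eh + 1))
        left = int(rng.integers(0, W - ew + 1))
        arr[:, top:top + eh, left:left + ew] = 0.0
    return arr


# ---------------------------------------------------------------------------
# synthetic CT-like image generator
# ---------------------------------------------------------------------------

def _bean(X, Y, rng):
    """Bright kidney-bean mask (ellipse with a hilum notch), jittered."""
    ang = rng.uniform(-0.35, 0.35)
    ca, sa = math.cos(ang), math.sin(ang)
    cx, cy = rng.uniform(-0.06, 0.06, size=2)
    sc = rng.uniform(0.85, 1.05)
    x = (ca * (X - cx) + sa * (Y - cy)) / sc
    y = (-sa * (X - cx) + ca * (Y - cy)) / sc
    body = (x / 0.58) ** 2 + (y / 0.40) ** 2 <= 1.0
    notch = ((x - 0.45) / 0.22) ** 2 + (y / 0.26) ** 2 <= 1.0
    return body & ~notch, (cx, cy, sc, ang)


def _interior_point(rng, geom):
    """A point well inside the bean body, away from the notched side."""
    cx, cy, sc, ang = geom
    t = rng.uniform(0.55 * math.pi, 1.45 * math.pi)
    r = rng.uniform(0.0, 0.45)
    bx, by = 0.58 * sc * r * math.cos(t), 0.40 * sc * r * math.sin(t)
    ca, sa = math.cos(ang), math.sin(ang)
    return cx + ca * bx - sa * by, cy + sa * bx + ca * by


def _boundary_point(rng, geom):
    """A point on the bean's outer edge (away from the notch)."""
    cx, cy, sc, ang = geom
    t = rng.uniform(0.6 * math.pi, 1.4 * math.pi)
    bx, by = 0.58 * sc * math.cos(t), 0.40 * sc * math.sin(t)
    ca, sa = math.cos(ang), math.sin(ang)
    return cx + ca * bx - sa * by, cy + sa * bx + ca * by


def render_synthetic_image(label: str, size: int, noise_sd: float,
                           rng: np.random.Generator) -> np.ndarray:
    """One grayscale CT-like image (uint8 [size, size]) for ``label``.

    Morphologies (all on a noisy dark background with a bright bean-shaped
    kidney): Normal = bean only; Cyst = bean + dark circular inclusion with
    a sharp bright rim; Stone = bean + small saturated-bright speck;
    Tumor = bean + irregular mid-intensity blob crossing the bean boundary.
    """
    S = size
    ax = (np.arange(S) - (S - 1) / 2) / (S / 2)
    X, Y = np.meshgrid(ax, ax)
    mask, geom = _bean(X, Y, rng)
    field = np.full((S, S), 28.0)
    field[mask] = 150.0 + rng.normal(0.0, 5.0)

    sharp = np.zeros((S, S))  # painted after smoothing (crisp structures)
    if label == "Cyst":
        px, py = _interior_point(rng, geom)
        r = rng.uniform(0.11, 0.17)
        d = np.sqrt((X - px) ** 2 + (Y - py) ** 2)
        field[d <= r] = 38.0
        rim = np.abs(d - r) <= (2.0 / (S / 2))
        sharp[rim & mask] = 205.0
    elif label == "Stone":
        px, py = _interior_point(rng, geom)
        r = rng.uniform(0.035, 0.055)
        d = np.sqrt((X - px) ** 2 + (Y - py) ** 2)
        sharp[d <= r] = 255.0
    elif label == "Tumor":
        px, py = _boundary_point(rng, geom)
        r0 = rng.uniform(0.17, 0.25)
        amp = rng.uniform(0.15, 0.35, size=4)
        phase = rng.uniform(0.0, 2 * math.pi, size=4)
        theta = np.arctan2(Y - py, X - px)
        wobble = 1.0 + sum(
            a * np.cos((k + 2) * theta + p)
            for k, (a, p) in enumerate(zip(amp, phase))
        ) * 0.3
        d = np.sqrt((X - px) ** 2 + (Y - py) ** 2)
        blob = d <= r0 * wobble
        field[blob] = 95.0 + rng.normal(0.0, 4.0)
    elif label != "Normal":
        raise ValueError(f"unknown class label {label!r}")

    field = gaussian_filter(field, sigma=max(1.0, 0.012 * S))
    field = np.where(sharp > 0, sharp, field)
    img = field + rng.normal(0.0, noise_sd, size=(S, S))
    return np.clip(img, 0, 255).astype(np.uint8)


def generate_synthetic_dataset(class_counts: dict[str, int] | None = None,
                               image_size: int = 128, noise_sd: float = 8.0,
                               seed: int = 0, out_dir=None) -> DatasetManifest:
    """Write a folder-per-class tree of synthetic PNGs and return its
    manifest.  Deterministic under ``seed`` (byte-identical files)."""
    if class_counts is None:
        class_counts = dict(PAPER_CLASS_COUNTS)
    norm_counts = {}
    for k, v in class_counts.items():
        key = k.capitalize()
        if key not in CLASSES:
            raise ValueError(f"unknown class {k!r}; expected one of {CLASSES}")
        if v < 0:
            raise ValueError("class counts must be non-negative")
        norm_counts[key] = int(v)
    if out_dir is None:
        raise ValueError("out_dir is required")
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory {out_dir} is not writable: {exc}") from exc

    records = []
    for ci, cls in enumerate(CLASSES):
        n = norm_counts.get(cls, 0)
        cdir = out_dir / cls
        if n:
            cdir.mkdir(exist_ok=True)
        for i in range(n):
            rng = np.random.default_rng(np.random.SeedSequence((seed, ci, i)))
            img = render_synthetic_image(cls, image_size, noise_sd, rng)
            path = cdir / f"{cls.lower()}_{i:05d}.png"
            Image.fromarray(img, mode="L").save(path)
            records.append((str(path), cls))
    return DatasetManifest.from_records(records, str(out_dir), CLASSES)


# ---------------------------------------------------------------------------
# batch loader
# ---------------------------------------------------------------------------

class ImageBatchLoader:
    """Seeded single-worker loader over a manifest.

    ``duplication=k`` exposes ``k * len(manifest)`` logical samples, each
    passing independently through the stochastic transforms (training mode)
    or the deterministic resize/crop/normalize pipeline (eval mode).
    """

    def __init__(self, manifest: DatasetManifest,
                 cfg: AugmentationConfig | None = None, batch_size: int = 32,
                 training: bool = True, duplication: int = 1, seed: int = 0,
                 shuffle: bool | None = None):
        if batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        self.manifest = manifest
        self.cfg = cfg if cfg is not None else AugmentationConfig()
        self.batch_size = batch_size
        self.training = training
        self.duplication = duplication
        self.seed = seed
        self.shuffle = training if shuffle is None else shuffle
        self.n_logical = augmented_size(len(manifest), duplication)
        self._class_index = {c: i for i, c in enumerate(manifest.classes)}

    def __len__(self) -> int:
        return self.n_logical

    @property
    def num_batches(self) -> int:
        return math.ceil(self.n_logical / self.batch_size)

    def labels(self) -> np.ndarray:
        """Integer labels in logical (unshuffled) order."""
        base = np.array(
            [self._class_index[lab] for _, lab in self.manifest.records],
            dtype=np.int64,
        )
        return np.tile(base, self.duplication)

    def batches(self, epoch: int = 0):
        order = np.arange(self.n_logical)
        if self.shuffle:
            rng = np.random.default_rng(
                np.random.SeedSequence((self.seed, epoch, 0xD47A))
            )
            rng.shuffle(order)
        n_rec = len(self.manifest)
        for start in range(0, self.n_logical, self.batch_size):
            chunk = order[start:start + self.batch_size]
            images, labels = [], []
            for li in chunk:
                path, lab = self.manifest.records[int(li) % n_rec]
                s = np.random.SeedSequence((self.seed, epoch, int(li)))
                images.append(
                    apply_transforms(path, self.cfg, seed=s, training=self.training)
                )
                labels.append(self._class_index[lab])
            yield np.stack(images), np.asarray(labels, dtype=np.int64)
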