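"""Image preprocessing for the histopathology classification pipeline.

Covers the ingest contract (RGB patches resized to 128x128x3 with bicubic
interpolation), the four per-image intensity scaling transforms, stochastic
label-preserving augmentation, augmentation-based class balancing, and the
nested train/validation/test partitioning (0.85 twice, i.e. 72.25% /
12.75% / 15%).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "ImageRecord",
    "AugmentationConfig",
    "SplitDataset",
    "DegenerateImageWarning",
    "resize_image",
    "scale_image",
    "augment_image",
    "balance_by_augmentation",
    "partition_dataset",
    "load_image_folder",
    "save_image_folder",
    "write_split_manifest",
    "TARGET_SHAPE",
    "SCALING_METHODS",
]

TARGET_SHAPE = (128, 128, 3)

SCALING_METHODS = ("normalize", "standard", "minmax", "maxabs")


class DegenerateImageWarning(UserWarning):
    """A scaling denominator vanished (constant or all-zero image)."""


@dataclass(eq=False)  # identity comparison; pixel arrays make __eq__ ambiguous
class ImageRecord:
    """One labelled image: ``pixels`` is an H x W x 3 array."""

    pixels: np.ndarray
    label: str
    provenance: str = "synthetic"


@dataclass(frozen=True)
class AugmentationConfig:
    """Magnitudes of the stochastic augmentation operators.

    Shifts / shear / zoom are fractions of the image size in [0, 0.25];
    rotation is the maximal angle in degrees (0-45); ``brightness`` is a
    (low, high) multiplier pair within [0.5, 2.0].  At augmentation time a
    concrete parameter is drawn uniformly within each magnitude.
    """

    rotation_deg: float = 0.0
    width_shift: float = 0.0
    height_shift: float = 0.0
    shear: float = 0.0
    zoom: float = 0.0
    brightness: tuple[float, float] = (1.0, 1.0)
    horizontal_flip: bool = False
    vertical_flip: bool = False

    def __post_init__(self) -> None:
        for name in ("width_shift", "height_shift", "shear", "zoom"):
            v = getattr(self, name)
            if not 0.0 <= v <= 0.25:
                raise ValueError(f"{name} must lie in [0, 0.25], got {v}")
        if not 0.0 <= self.rotation_deg <= 45.0:
            raise ValueError(f"rotation_deg must lie in [0, 45], got {self.rotation_deg}")
        lo, hi = self.brightness
        if not (0.5 <= lo <= hi <= 2.0):
            raise ValueError(f"brightness bounds must satisfy 0.5 <= low <= high <= 2.0, got {self.brightness}")

    @classmethod
    def balancing_defaults(cls) -> "AugmentationConfig":
        """The fixed operator magnitudes used for class balancing."""
        return cls(
            rotation_deg=30.0,
            width_shift=0.2,
            height_shift=0.2,
            shear=0.2,
            zoom=0.2,
            brightness=(0.8, 1.2),
            horizontal_flip=True,
            vertical_flip=True,
        )

    def to_dict(self) -> dict:
        return {
            "rotation_deg": self.rotation_deg,
            "width_shift": self.width_shift,
            "height_shift": self.height_shift,
            "shear": self.shear,
            "zoom": self.zoom,
            "brightness": tuple(self.brightness),
            "horizontal_flip": self.horizontal_flip,
            "vertical_flip": self.vertical_flip,
        }


@dataclass
class SplitDataset:
    """Disjoint train / validation / test record collections."""

    train: list
    validation: list
    test: list

    def __iter__(self):
        yield from (self.train, self.validation, self.test)

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.validation), len(self.test))


def resize_image(image: ImageRecord, target: tuple[int, int, int] = TARGET_SHAPE) -> ImageRecord:
    """Resize to ``target`` (H, W, 3) in RGB space with bicubic interpolation."""
    px = np.asarray(image.pixels)
    if px.ndim != 3 or px.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {px.shape}")
    h, w, _ = target
    pil = Image.fromarray(px.astype(np.uint8), mode="RGB")
    out = pil.resize((w, h), resample=Image.BICUBIC)
    return replace(image, pixels=np.asarray(out, dtype=np.uint8))


def scale_image(image, method: str):
    """Apply one of the four per-image intensity scalings.

    ``normalize``   -> X / max(X)
    ``standard``    -> (X - mean) / std
    ``minmax``      -> (X - min) / (max - min)
    ``maxabs``      -> X / |max(X)|

    Statistics are taken over all pixels of the single image.  Degenerate
    denominators (constant image for standard/minmax, all-zero maximum for
    normalize/maxabs) produce an all-zero image and a
    :class:`DegenerateImageWarning` instead of an error.

    Accepts either an :class:`ImageRecord` (returned as a record) or a bare
    array (returned as an array of floats).
    """
    record = isinstance(image, ImageRecord)
    px = np.asarray(image.pixels if record else image, dtype=float)
    if px.size == 0:
        raise ValueError("empty image")
    if method in ("normalize", "maxabs"):
        denom = px.max() if method == "normalize" else np.abs(px).max()
        if denom == 0:
            warnings.warn("all-zero image: scaling denominator is zero", DegenerateImageWarning)
            out = np.zeros_like(px)
        else:
            out = px / denom
    elif method == "standard":
        sd = px.std()
        if sd == 0:
            warnings.warn("constant image: zero standard deviation", DegenerateImageWarning)
            out = np.zeros_like(px)
        else:
            out = (px - px.mean()) / sd
    elif method == "minmax":
        lo, hi = px.min(), px.max()
        if hi == lo:
            warnings.warn("constant image: zero min-max range", DegenerateImageWarning)
            out = np.zeros_like(px)
        else:
            out = (px - lo) / (hi - lo)
    else:
        raise ValueError(f"unknown scaling method {method!r}; choose from {SCALING_METHODS}")
    return replace(image, pixels=out) if record else out


def _affine_matrix(angle_deg: float, shear: float, zoom: float, h: int, w: int) -> np.ndarray:
    theta = np.deg2rad(angle_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    shr = np.array([[1.0, shear], [0.0, 1.0]])
    zm = np.array([[zoom, 0.0], [0.0, zoom]])
    return rot @ shr @ zm


def augment_image(image: ImageRecord, config: AugmentationConfig, rng: np.random.Generator) -> ImageRecord:
    """Apply one random draw of the configured augmentation operators.

    Rotation angle, shifts and shear are drawn uniformly in +/- the
    configured magnitude; zoom in ``[1 - z, 1 + z]``; brightness in the
    configured (low, high) interval; each enabled flip is applied with
    probability 1/2.  Exposed borders are filled with nearest-edge values.
    The label is never changed.
    """
    px = np.asarray(image.pixels, dtype=float)
    h, w, _ = px.shape

    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    dy = rng.uniform(-config.height_shift, config.height_shift) * h
    dx = rng.uniform(-config.width_shift, config.width_shift) * w
    shear = rng.uniform(-config.shear, config.shear)
    zoom = rng.uniform(1.0 - config.zoom, 1.0 + config.zoom)
    bright = rng.uniform(config.brightness[0], config.brightness[1])
    do_h = config.horizontal_flip and rng.random() < 0.5
    do_v = config.vertical_flip and rng.random() < 0.5

    mat = _affine_matrix(angle, shear, zoom, h, w)
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    offset = center - mat @ center + np.array([dy, dx])
    identity = np.allclose(mat, np.eye(2)) and np.allclose(offset, 0.0)
    if identity:
        out = px.copy()
    else:
        out = np.stack(
            [
                ndimage.affine_transform(px[:, :, c], mat, offset=offset, order=1, mode="nearest")
                for c in range(3)
            ],
            axis=2,
        )
    if do_h:
        out = out[:, ::-1, :]
    if do_v:
        out = out[::-1, :, :]
    out = np.clip(out * bright, 0, 255)
    return replace(image, pixels=out.astype(image.pixels.dtype, copy=False))


def balance_by_augmentation(
    records: Sequence[ImageRecord],
    config: AugmentationConfig | None = None,
    seed: int = 0,
) -> list[ImageRecord]:
    """Equalize class sizes by appending augmented copies of originals.

    Every class is raised to the size of the largest class; originals are
    always retained.  Source images are sampled uniformly (with
    replacement) from the class's originals.
    """
    if config is None:
        config = AugmentationConfig.balancing_defaults()
    by_class: dict[str, list[ImageRecord]] = {}
    for r in records:
        by_class.setdefault(r.label, []).append(r)
    if not by_class or any(len(v) == 0 for v in by_class.values()):
        raise ValueError("every class must contain at least one image")
    target = max(len(v) for v in by_class.values())
    rng = np.random.default_rng(seed)
    out = list(records)
    for label in sorted(by_class):
        members = by_class[label]
        for _ in range(target - len(members)):
            src = members[int(rng.integers(len(members)))]
            aug = augment_image(src, config, rng)
            out.append(replace(aug, provenance=f"aug:{src.provenance}"))
    return out


def partition_dataset(records: Sequence, ratio: float = 0.85, seed: int = 0) -> SplitDataset:
    """Nested random split: ``ratio`` to a train+validation pool and the rest
    to test, then ``ratio`` of the pool to train and the rest to validation.

    With the default 0.85 this yields 72.25% / 12.75% / 15%.  Assignment is
    class-agnostic and seeded.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    n = len(records)
    if n < 3:
        raise ValueError("need at least 3 records to populate all three parts")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_pool = int(round(n * ratio))
    n_train = int(round(n_pool * ratio))
    if n_train == 0 or n_pool - n_train == 0 or n - n_pool == 0:
        raise ValueError(f"dataset of {n} records too small for a {ratio} nested split")
    pool, test_idx = order[:n_pool], order[n_pool:]
    train_idx, val_idx = pool[:n_train], pool[n_train:]
    take = lambda idx: [records[i] for i in idx]
    return SplitDataset(train=take(train_idx), validation=take(val_idx), test=take(test_idx))


# --- directory-per-class IO ------------------------------------------------

def load_image_folder(root, resize: bool = True) -> list[ImageRecord]:
    """Read a directory-per-class tree of PNG/JPEG files."""
    root = Path(root)
    records = []
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for f in sorted(class_dir.iterdir()):
            if f.suffix.lower() not in (".png", ".jpg", ".jpeg"):
                continue
            px = np.asarray(Image.open(f).convert("RGB"), dtype=np.uint8)
            rec = ImageRecord(pixels=px, label=class_dir.name, provenance=str(f))
            records.append(resize_image(rec) if resize else rec)
    if not records:
        raise ValueError(f"no images found under {root}")
    return records


def save_image_folder(records: Sequence[ImageRecord], root) -> None:
    """Write records back out in the same directory-per-class PNG layout."""
    root = Path(root)
    counters: dict[str, int] = {}
    for r in records:
        d = root / r.label
        d.mkdir(parents=True, exist_ok=True)
        i = counters.get(r.label, 0)
        counters[r.label] = i + 1
        px = np.clip(np.asarray(r.pixels), 0, 255).astype(np.uint8)
        Image.fromarray(px, mode="RGB").save(d / f"{i:06d}.png")


def write_split_manifest(split: SplitDataset, path) -> None:
    """CSV manifest of (provenance, class, split) for every record."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "class", "split"])
        for name, part in zip(("train", "validation", "test"), split):
            for r in part:
                w.writerow([r.provenance, r.label, name])
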