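"""Seeded synthetic image sets and benchmark objectives.

The generator emulates only the *contract* of two-class histopathology
patch collections — 8-bit RGB images of a fixed size with a
class-distinguishing signal of controllable strength — not the appearance
statistics of stained tissue.  Class 0 is a smooth textured background;
class 1 additionally carries dark elliptical blobs (a crude stand-in for
elevated nuclear density) whose amplitude scales with ``separability``.
At separability 0 both classes are draws from the same distribution.

Benchmark objectives (sphere, Rastrigin) are defined on ``[0, 1]^D`` as
maximization problems with their optimum (value 0) at the center of the
hypercube; they exist so the optimizers can be validated against known
landscapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .preprocessing import ImageRecord, save_image_folder

__all__ = [
    "SyntheticImageSpec",
    "make_synthetic_imageset",
    "write_synthetic_imageset",
    "benchmark_objective",
    "CLASS_NAMES",
]

#: Class labels mirroring the two-category histopathology layout.
CLASS_NAMES = ("normal", "OSCC")


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Parameters of a two-class synthetic image set.

    Defaults mirror the study conditions: class sizes (2494, 2698) and
    128 x 128 RGB patches.  ``separability`` in [0, 1] scales the
    class-specific blob signal; ``noise_sd`` is additive Gaussian pixel
    noise in 8-bit intensity units.
    """

    n_per_class: tuple[int, int] = (2494, 2698)
    size: tuple[int, int] = (128, 128)
    separability: float = 1.0
    noise_sd: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.n_per_class):
            raise ValueError("need at least one image per class")
        if not 0.0 <= self.separability <= 1.0:
            raise ValueError("separability must lie in [0, 1]")


def _background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency texture with a pinkish base tone."""
    coarse = rng.normal(0.0, 1.0, size=(max(h // 16, 2), max(w // 16, 2)))
    texture = ndimage.zoom(coarse, (h / coarse.shape[0], w / coarse.shape[1]), order=1)
    base = np.array([200.0, 170.0, 185.0])  # per-channel mean intensity
    img = base[None, None, :] + 18.0 * texture[:, :, None]
    return img


def _add_blobs(img: np.ndarray, amplitude: float, rng: np.random.Generator) -> None:
    """Darken k random elliptical regions in place."""
    h, w, _ = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    n_blobs = int(rng.integers(8, 16))
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        ry, rx = rng.uniform(h * 0.07, h * 0.18, size=2)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cy, xx - cx
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        mask = (u / ry) ** 2 + (v / rx) ** 2 <= 1.0
        # purple-dark blobs: green absorbed most, as in basophilic staining
        img[mask] -= amplitude * np.array([0.7, 1.25, 0.8])


def make_synthetic_imageset(spec: SyntheticImageSpec) -> list[ImageRecord]:
    """Generate the two-class set described by ``spec`` (fully seeded)."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.size
    amplitude = 70.0 * spec.separability
    records: list[ImageRecord] = []
    for label, n in zip(CLASS_NAMES, spec.n_per_class):
        for i in range(n):
            img = _background(h, w, rng)
            if label == CLASS_NAMES[1] and amplitude > 0:
                _add_blobs(img, amplitude, rng)
            img += rng.normal(0.0, spec.noise_sd, size=img.shape)
            px = np.clip(img, 0, 255).astype(np.uint8)
            records.append(ImageRecord(pixels=px, label=label, provenance=f"synthetic:{label}:{i}"))
    return records


def write_synthetic_imageset(spec: SyntheticImageSpec, root) -> list[ImageRecord]:
    """Generate and write the set in the directory-per-class PNG layout."""
    records = make_synthetic_imageset(spec)
    save_image_folder(records, root)
    return records


def benchmark_objective(name: str, D: int) -> Callable[[np.ndarray], float]:
    """Benchmark fitness callable on ``[0, 1]^D`` (maximization, optimum 0).

    ``sphere``:    -sum((x - 0.5)^2)
    ``rastrigin``: the standard Rastrigin landscape with [0, 1] mapped onto
                   [-5.12, 5.12] per coordinate, negated.
    """
    if D < 1:
        raise ValueError("D must be >= 1")
    if name == "sphere":

        def sphere(x: np.ndarray) -> float:
            x = np.asarray(x, dtype=float)
            return -float(np.sum((x - 0.5) ** 2))

        return sphere
    if name == "rastrigin":

        def rastrigin(x: np.ndarray) -> float:
            z = (np.asarray(x, dtype=float) - 0.5) * 10.24
            return -float(10.0 * D + np.sum(z**2 - 10.0 * np.cos(2.0 * np.pi * z)))

        return rastrigin
    raise ValueError(f"unknown benchmark objective {name!r}")
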