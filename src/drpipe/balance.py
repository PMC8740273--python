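"""Class balancing: upsampling counts, geometric transforms, class weights.

Diabetic-retinopathy datasets are heavily skewed toward grade 0 (no
disease). Two remedies are implemented:

* **Upsampling** — each image of a minority class is replicated
  ``Add_i = floor((N0 - N_i) / N_i)`` times via three geometric transforms
  (left-right flip, up-down flip, random-angle rotation about the image
  centre), bringing class ``i`` from ``N_i`` to ``N_i * (Add_i + 1)``
  images, just below the majority size ``N0``. Rotation can push bright
  pixels outside the retinal circle, so every generated image is re-masked.

* **Class weights** — ``w_c = n_samples / (n_classes * count_c)``, used as
  per-class loss weights so minority errors cost proportionally more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import rotate as _sk_rotate

from .errors import InvalidCounts, MissingClass, NotSquare
from .imaging import as_pixel_grid, inscribe_circle_mask

__all__ = [
    "BalancePlan",
    "ClassWeights",
    "Provenance",
    "AugmentedSet",
    "compute_balance_plan",
    "flip_lr",
    "flip_ud",
    "rotate_by_angle",
    "rotate_random",
    "remove_unnecessary_area",
    "upsample_class",
    "class_weights",
]

N_GRADES = 5


@dataclass(frozen=True)
class BalancePlan:
    """Per-class upsampling counts and resulting totals.

    ``add_per_image[i] = floor((majority_count - class_counts[i]) / class_counts[i])``
    and ``resulting_totals[i] = class_counts[i] * (add_per_image[i] + 1)``.
    """

    majority_count: int
    class_counts: tuple[int, ...]
    add_per_image: tuple[int, ...]
    resulting_totals: tuple[int, ...]


@dataclass(frozen=True)
class ClassWeights:
    """One positive loss weight per grade; minority grades weigh more."""

    weights: tuple[float, ...]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.weights, dtype=float)


@dataclass(frozen=True)
class Provenance:
    """Where an augmented image came from.

    ``transform`` is ``"source"`` for originals and one of
    ``{"flip_lr", "flip_ud", "rotate"}`` for generated images;
    ``angle_deg`` is set only for rotations.
    """

    source_index: int
    transform: str
    angle_deg: float | None = None


@dataclass
class AugmentedSet:
    """Originals plus generated images, with per-image provenance."""

    images: list[np.ndarray]
    labels: list[int]
    provenance: list[Provenance] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.images)


def compute_balance_plan(majority_count: int, class_counts: Sequence[int]) -> BalancePlan:
    """Compute floored per-image add counts for each minority class.

    Raises
    ------
    InvalidCounts
        If any class count is below 1 or exceeds the majority count.
    """
    counts = tuple(int(c) for c in class_counts)
    n0 = int(majority_count)
    for c in counts:
        if c < 1:
            raise InvalidCounts(f"class count must be >= 1, got {c}")
        if c > n0:
            raise InvalidCounts(f"class count {c} exceeds majority count {n0}")
    add = tuple((n0 - c) // c for c in counts)
    totals = tuple(c * (a + 1) for c, a in zip(counts, add))
    return BalancePlan(n0, counts, add, totals)


def flip_lr(image: np.ndarray) -> np.ndarray:
    """Mirror about the vertical centreline (reverse column order)."""
    return as_pixel_grid(image)[:, ::-1].copy()


def flip_ud(image: np.ndarray) -> np.ndarray:
    """Mirror about the horizontal centreline (reverse row order)."""
    return as_pixel_grid(image)[::-1].copy()


def rotate_by_angle(image: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate about the image centre; out-of-frame regions fill with 0."""
    image = as_pixel_grid(image)
    out = _sk_rotate(image, angle_deg, resize=False, order=1, preserve_range=True, cval=0)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def rotate_random(image: np.ndarray, rng_seed: int | np.random.Generator = 0) -> np.ndarray:
    """Rotate by an angle drawn uniformly from [0, 360) degrees.

    Deterministic given the seed; accepts a ``numpy.random.Generator`` for
    callers that manage their own stream.
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    return rotate_by_angle(image, float(rng.uniform(0.0, 360.0)))


def remove_unnecessary_area(image: np.ndarray) -> np.ndarray:
    """Re-apply the inscribed-circle mask to a square image.

    Rotation fills frame corners with interpolated bright pixels; this
    zeroes everything outside the circle again.

    Raises
    ------
    NotSquare
        If the image is not square (upsampling runs after preprocessing,
        which always yields square images).
    """
    image = as_pixel_grid(image)
    if image.shape[0] != image.shape[1]:
        raise NotSquare(f"expected a square image, got {image.shape[0]}x{image.shape[1]}")
    return inscribe_circle_mask(image)


def upsample_class(
    images: Sequence[np.ndarray],
    add_per_image: int,
    rng_seed: int | np.random.Generator = 0,
    label: int = 0,
) -> AugmentedSet:
    """Expand a class by *add_per_image* generated images per original.

    The generated sequence per source is deterministic: left-right flip
    first, up-down flip second, and the remainder independent random-angle
    rotations. Every generated image is re-masked with
    :func:`remove_unnecessary_area`. Output size is
    ``len(images) * (add_per_image + 1)``.
    """
    if add_per_image < 0:
        raise ValueError(f"add_per_image must be >= 0, got {add_per_image}")
    rng = np.random.default_rng(rng_seed) if not isinstance(rng_seed, np.random.Generator) else rng_seed
    out = AugmentedSet(images=[], labels=[], provenance=[])
    for idx, src in enumerate(images):
        src = as_pixel_grid(src)
        out.images.append(src)
        out.labels.append(label)
        out.provenance.append(Provenance(idx, "source"))
        for k in range(add_per_image):
            if k == 0:
                gen, tag, angle = flip_lr(src), "flip_lr", None
            elif k == 1:
                gen, tag, angle = flip_ud(src), "flip_ud", None
            else:
                angle = float(rng.uniform(0.0, 360.0))
                gen, tag = rotate_by_angle(src, angle), "rotate"
            out.images.append(remove_unnecessary_area(gen))
            out.labels.append(label)
            out.provenance.append(Provenance(idx, tag, angle))
    return out


def class_weights(labels: Sequence[int], n_classes: int = N_GRADES) -> ClassWeights:
    """Inverse-frequency loss weights ``w_c = total / (n_classes * count_c)``.

    Raises
    ------
    MissingClass
        If any of the ``n_classes`` grades has no examples.
    """
    y = np.asarray(labels, dtype=int)
    counts = np.bincount(y, minlength=n_classes)
    if counts.size > n_classes:
        raise MissingClass(f"labels exceed the expected {n_classes} classes")
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        raise MissingClass(f"classes with zero examples: {missing.tolist()}")
    w = y.size / (n_classes * counts.astype(float))
    return ClassWeights(tuple(w.tolist()))
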