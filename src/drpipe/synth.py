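"""Synthetic fixtures: fundus-like images, skewed label sets, and
skill-controlled probability matrices.

The image generator emulates the geometry the preprocessing chain relies
on — a near-black frame (every channel strictly below the dark threshold
of 7) surrounding a bright, roughly elliptical "retina" with optional
bright lesion blobs — not retinal biology. Severity grades modulate disc
intensity and lesion count so that even a tiny classifier can learn the
classes. Label sets reproduce the heavy class skew of real grading data
(about 73 : 7 : 15 : 2.5 : 2 across grades 0-4).

The probability-matrix generator emulates base classifiers of controlled
skill: classifier i predicts the true class with probability ``skill`` and
a uniformly random wrong class otherwise, concentrating ``concentration``
of the probability mass on its chosen class.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from skimage.draw import disk as _sk_disk
from skimage.draw import ellipse as _sk_ellipse

from .datasets import LabeledDataset, write_manifest
from .imaging import save_image

__all__ = [
    "FundusParams",
    "SkillParams",
    "make_fundus",
    "make_labelled_set",
    "make_prob_matrices",
    "SKEWED_PROPORTIONS",
]

#: Class proportions of a typical five-grade retinopathy dataset.
SKEWED_PROPORTIONS: tuple[float, ...] = (0.7347, 0.0695, 0.1507, 0.0249, 0.0202)

N_GRADES = 5


@dataclass(frozen=True)
class FundusParams:
    """Geometry and intensity ranges of the synthetic fundus images.

    ``border`` pixels of frame on each side stay strictly below intensity
    7; the elliptical disc fills most of the interior with intensity drawn
    from ``disc_intensity``; ``lesion_count`` bright blobs of intensity
    ``lesion_intensity`` land inside the disc.
    """

    side: int = 96
    border: int = 8
    disc_intensity: tuple[int, int] = (80, 200)
    lesion_count: tuple[int, int] = (0, 4)
    lesion_intensity: int = 230
    seed: int = 0

    def __post_init__(self) -> None:
        if self.border < 0:
            raise ValueError("border must be >= 0")
        if self.side - 2 * self.border < 8:
            raise ValueError("canvas too small for the requested border")
        lo, hi = self.disc_intensity
        if not (7 <= lo <= hi <= 255):
            raise ValueError("disc intensity range must lie within [7, 255]")


@dataclass(frozen=True)
class SkillParams:
    """Controls one synthetic base classifier.

    ``skill`` is its probability of picking the true class;
    ``concentration`` the probability mass placed on the picked class
    (the rest spreads uniformly).
    """

    skill: float
    concentration: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.skill <= 1.0:
            raise ValueError("skill must lie in [0, 1]")
        if not 0.0 <= self.concentration <= 1.0:
            raise ValueError("concentration must lie in [0, 1]")


def make_fundus(
    params: FundusParams,
    rng: np.random.Generator | None = None,
    disc_intensity: int | None = None,
    lesion_count: int | None = None,
) -> np.ndarray:
    """Render one fundus-like RGB image; deterministic under the seed.

    *disc_intensity* and *lesion_count* override the sampled values (used
    by :func:`make_labelled_set` to encode the grade).
    """
    rng = np.random.default_rng(params.seed) if rng is None else rng
    s = params.side
    img = np.zeros((s, s, 3), dtype=np.uint8)
    img[:, :, :] = rng.integers(0, 7, size=(s, s, 3), dtype=np.uint8)

    base = disc_intensity if disc_intensity is not None else int(
        rng.integers(params.disc_intensity[0], params.disc_intensity[1] + 1)
    )
    half = (s - 2 * params.border) / 2.0
    # random eccentricity exercises the non-square trimming paths
    ry = half * rng.uniform(0.8, 1.0)
    rx = half * rng.uniform(0.8, 1.0)
    cy = cx = (s - 1) / 2.0
    rr, cc = _sk_ellipse(cy, cx, ry, rx, shape=(s, s))
    noise = rng.integers(-8, 9, size=rr.size)
    red = np.clip(base + noise, 7, 255)
    img[rr, cc, 0] = red.astype(np.uint8)
    img[rr, cc, 1] = np.clip(red * 0.55, 0, 255).astype(np.uint8)
    img[rr, cc, 2] = np.clip(red * 0.25, 0, 255).astype(np.uint8)

    k = lesion_count if lesion_count is not None else int(
        rng.integers(params.lesion_count[0], params.lesion_count[1] + 1)
    )
    inner = min(ry, rx)
    for _ in range(k):
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(0, inner * 0.6)
        ly, lx = cy + dist * np.sin(ang), cx + dist * np.cos(ang)
        lr = rng.uniform(1.0, max(1.5, s / 24.0))
        rr2, cc2 = _sk_disk((ly, lx), lr, shape=(s, s))
        img[rr2, cc2, 0] = params.lesion_intensity
        img[rr2, cc2, 1] = np.uint8(params.lesion_intensity * 0.8)
    return img


def _grade_appearance(grade: int) -> tuple[int, tuple[int, int]]:
    """Disc intensity and lesion-count range encoding a severity grade."""
    intensity = 60 + 35 * grade
    lesions = (2 * grade, 2 * grade + 1) if grade > 0 else (0, 0)
    return intensity, lesions


def make_labelled_set(
    n_per_class: Sequence[int],
    params: FundusParams,
    seed: int,
    out_dir: str | Path,
) -> LabeledDataset:
    """Write a class-skewed image tree plus manifest; return the dataset.

    Grade g images get disc intensity 60 + 35g and about 2g lesions, so
    the five classes are visually separable at tiny scale. Per-class
    counts are exact; images are byte-identical under the same seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    entries: list[tuple[str, int]] = []
    for grade, count in enumerate(n_per_class):
        intensity, lesion_range = _grade_appearance(grade)
        for i in range(count):
            k = int(rng.integers(lesion_range[0], lesion_range[1] + 1))
            img = make_fundus(params, rng=rng, disc_intensity=intensity, lesion_count=k)
            rel = f"grade{grade}_{i:04d}.png"
            save_image(img, out_dir / rel)
            entries.append((rel, grade))
    ds = LabeledDataset(tuple(entries))
    write_manifest(ds, out_dir / "manifest.csv")
    return ds


def make_prob_matrices(
    true_labels,
    skills: Sequence[SkillParams],
    seed: int = 0,
    n_classes: int = N_GRADES,
) -> list[np.ndarray]:
    """Per-classifier probability matrices with controlled skill.

    Each row is ``(1 - concentration)/K`` everywhere plus ``concentration``
    on the classifier's chosen class, so rows sum to 1 exactly.
    """
    y = np.asarray(true_labels, dtype=int)
    rng = np.random.default_rng(seed)
    mats = []
    for sp in skills:
        correct = rng.random(y.size) < sp.skill
        offsets = rng.integers(1, n_classes, size=y.size)
        chosen = np.where(correct, y, (y + offsets) % n_classes)
        m = np.full((y.size, n_classes), (1.0 - sp.concentration) / n_classes)
        m[np.arange(y.size), chosen] += sp.concentration
        mats.append(m)
    return mats
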