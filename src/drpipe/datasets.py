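"""Label manifests and stratified 3:1:1 dataset splitting.

Manifests are two-column CSV files (``image,label``) mapping an image path
to a severity grade 0-4. The split follows a 3:1:1 train/valid/test ratio
with validation and test sizes fixed to ``ceil(N/5)`` each and the
remainder going to training (this rounding is what makes 35,126 images
split into 21,074 / 7,026 / 7,026). Assignment is a seeded, per-class
stratified shuffle: membership is random, the sizes are exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import BadLabel, MissingFile

__all__ = [
    "LabeledDataset",
    "SplitResult",
    "split_311",
    "read_manifest",
    "write_manifest",
]

N_GRADES = 5


@dataclass(frozen=True)
class LabeledDataset:
    """Image paths with their severity grades."""

    entries: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        paths = [p for p, _ in self.entries]
        if len(set(paths)) != len(paths):
            raise ValueError("manifest paths must be unique")
        for p, g in self.entries:
            if not 0 <= g < N_GRADES:
                raise BadLabel(f"label {g!r} for {p} outside grades 0-{N_GRADES - 1}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def paths(self) -> list[str]:
        return [p for p, _ in self.entries]

    @property
    def labels(self) -> np.ndarray:
        return np.asarray([g for _, g in self.entries], dtype=int)

    @property
    def class_counts(self) -> tuple[int, ...]:
        return tuple(np.bincount(self.labels, minlength=N_GRADES).tolist())

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(tuple(self.entries[i] for i in indices))


@dataclass(frozen=True)
class SplitResult:
    """Disjoint train/valid/test index lists covering the dataset."""

    train: tuple[int, ...]
    valid: tuple[int, ...]
    test: tuple[int, ...]

    @property
    def sizes(self) -> tuple[int, int, int]:
        return (len(self.train), len(self.valid), len(self.test))


def _apportion(quotas: np.ndarray, total: int) -> np.ndarray:
    """Integer allocation summing to *total*, by largest remainder.

    Each entry ends within one unit of its (possibly fractional) quota,
    except when the quota sum itself differs from *total* (at most a
    couple of units for the split's rounding rule).
    """
    base = np.floor(quotas).astype(int)
    frac = quotas - base
    short = int(total - base.sum())
    order = np.argsort(-frac, kind="stable")
    if short >= 0:
        base[order[:short]] += 1
    else:
        for idx in order[::-1]:
            if short == 0:
                break
            if base[idx] > 0:
                base[idx] -= 1
                short += 1
    return base


def split_311(dataset: LabeledDataset, rng_seed: int = 0) -> SplitResult:
    """Stratified 3:1:1 split with exact global sizes.

    Validation and test each receive ``ceil(N/5)`` samples; training the
    remainder. Per class, training receives a largest-remainder share of
    3/5 of the class (within one image), and the rest is split evenly
    between validation and test. Reproducible given the seed.
    """
    n = len(dataset)
    if n == 0:
        raise ValueError("cannot split an empty dataset")
    v = math.ceil(n / 5)
    t = n - 2 * v
    if t < 0:
        raise ValueError(f"dataset of size {n} too small for a 3:1:1 split")
    labels = dataset.labels
    classes = np.unique(labels)
    counts = np.array([(labels == c).sum() for c in classes])
    train_alloc = _apportion(0.6 * counts.astype(float), t)
    train_alloc = np.minimum(train_alloc, counts)
    rest = counts - train_alloc
    valid_alloc = _apportion(rest / 2.0, v)
    valid_alloc = np.minimum(valid_alloc, rest)
    rng = np.random.default_rng(rng_seed)
    train: list[int] = []
    valid: list[int] = []
    test: list[int] = []
    for c, tr, va in zip(classes, train_alloc, valid_alloc):
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        train.extend(idx[:tr].tolist())
        valid.extend(idx[tr : tr + va].tolist())
        test.extend(idx[tr + va :].tolist())
    return SplitResult(tuple(sorted(train)), tuple(sorted(valid)), tuple(sorted(test)))


def read_manifest(
    path: str | Path,
    check_files: str = "warn",
) -> LabeledDataset:
    """Read an ``image,label`` CSV manifest.

    Parameters
    ----------
    check_files:
        ``"warn"`` (default) emits a single warning listing how many
        referenced files are missing, ``"error"`` raises
        :class:`MissingFile`, ``"ignore"`` skips the check.
    """
    df = pd.read_csv(path)
    if not {"image", "label"}.issubset(df.columns):
        raise ValueError(f"manifest {path} must have columns image,label")
    labels = pd.to_numeric(df["label"], errors="coerce")
    bad = df.loc[labels.isna() | (labels % 1 != 0) | (labels < 0) | (labels >= N_GRADES)]
    if len(bad):
        raise BadLabel(f"labels outside 0-{N_GRADES - 1} in {path}: {bad['label'].tolist()[:5]}")
    entries = tuple(zip(df["image"].astype(str), labels.astype(int)))
    if check_files != "ignore":
        root = Path(path).parent
        missing = [p for p, _ in entries if not (Path(p).is_absolute() and Path(p).exists()) and not (root / p).exists()]
        if missing:
            msg = f"{len(missing)} of {len(entries)} manifest files missing (first: {missing[0]})"
            if check_files == "error":
                raise MissingFile(msg)
            warnings.warn(msg, stacklevel=2)
    return LabeledDataset(entries)


def write_manifest(dataset: LabeledDataset, path: str | Path) -> None:
    """Write the dataset as an ``image,label`` CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(dataset.entries, columns=["image", "label"]).to_csv(path, index=False)
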