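"""F1-weighted soft-voting ensemble with an amplification parameter.

Each base classifier i contributes a fusion weight

    lambda_i = F1_i / sum_p F1_p + (F1_i - mean(F1)) * n

where the F1 scores come from the validation set and the scalar ``n``
amplifies the gap between stronger and weaker classifiers. The weights
always sum to exactly 1 (the difference terms cancel), but individual
weights can go negative for large n — the formula is applied verbatim and
a warning is emitted when that happens.

Fused probabilities are the lambda-weighted sum of the per-classifier
probability matrices; the predicted grade is the argmax per sample (ties
to the lowest grade). ``n`` is chosen by a two-stage grid search —
coarse 10..100 in steps of 10, then fine 1..10 — maximising macro-F1 with
accuracy as tie-breaker and smaller n preferred.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import AllZeroF1, NegativeLambdaWarning, ShapeMismatch
from .metrics import aggregate_scores, confusion

__all__ = [
    "EnsembleWeights",
    "FusedPrediction",
    "NSearchResult",
    "compute_lambdas",
    "fuse",
    "select_n",
    "COARSE_GRID",
    "FINE_GRID",
]

#: First-stage amplification grid.
COARSE_GRID: tuple[int, ...] = tuple(range(10, 101, 10))
#: Second-stage amplification grid.
FINE_GRID: tuple[int, ...] = tuple(range(1, 11))


@dataclass(frozen=True)
class EnsembleWeights:
    """Per-classifier fusion weights for a given amplification n."""

    f1_list: tuple[float, ...]
    n: float
    lambdas: np.ndarray

    @property
    def q(self) -> int:
        return len(self.f1_list)


@dataclass(frozen=True)
class FusedPrediction:
    """Weighted-sum probabilities and the resulting grade per sample."""

    probabilities: np.ndarray
    grades: np.ndarray


@dataclass(frozen=True)
class NSearchResult:
    """Chosen amplification n and the full (stage, n, accuracy, macro-F1)
    score table of the two-stage grid search."""

    n: float
    table: pd.DataFrame


def compute_lambdas(f1_list: Sequence[float], n: float) -> EnsembleWeights:
    """Fusion weights from validation F1 scores and amplification n.

    Raises
    ------
    AllZeroF1
        If every F1 score is zero (the base term is undefined).

    Warns
    -----
    NegativeLambdaWarning
        If any weight goes negative (possible for large n); fusion is
        still applied verbatim, but fused rows may then leave [0, 1].
    """
    f1 = np.asarray(f1_list, dtype=float)
    if f1.ndim != 1 or f1.size < 1:
        raise ValueError("f1_list must be a non-empty 1-D sequence")
    if np.any((f1 < 0) | (f1 > 1)):
        raise ValueError(f"F1 scores must lie in [0, 1], got {f1}")
    if n < 0:
        raise ValueError(f"amplification n must be >= 0, got {n}")
    total = f1.sum()
    if total == 0:
        raise AllZeroF1("all F1 scores are zero; weights undefined")
    lam = f1 / total + (f1 - f1.mean()) * n
    if np.any(lam < 0):
        warnings.warn(
            f"negative fusion weight at n={n}: {lam}", NegativeLambdaWarning, stacklevel=2
        )
    return EnsembleWeights(tuple(f1.tolist()), float(n), lam)


def fuse(prob_matrices: Sequence[np.ndarray], weights: EnsembleWeights) -> FusedPrediction:
    """Weighted sum of per-classifier probabilities, argmax per sample.

    Ties in the argmax resolve to the lowest grade index.

    Raises
    ------
    ShapeMismatch
        If matrix count differs from the weight count or shapes disagree.
    """
    mats = [np.asarray(m, dtype=float) for m in prob_matrices]
    if len(mats) != weights.q:
        raise ShapeMismatch(f"{len(mats)} matrices for {weights.q} weights")
    shape = mats[0].shape
    if any(m.shape != shape for m in mats) or len(shape) != 2:
        raise ShapeMismatch(f"matrices must share one 2-D shape, got {[m.shape for m in mats]}")
    fused = np.zeros(shape)
    for lam, m in zip(weights.lambdas, mats):
        fused += lam * m
    return FusedPrediction(fused, np.argmax(fused, axis=1))


def select_n(
    f1_list: Sequence[float],
    prob_matrices: Sequence[np.ndarray],
    true_labels,
    coarse: Sequence[float] = COARSE_GRID,
    fine: Sequence[float] = FINE_GRID,
) -> NSearchResult:
    """Two-stage grid search for the amplification parameter n.

    Evaluates every n on the coarse grid then every n on the fine grid,
    scoring the fused predictions against *true_labels*. Returns the n
    maximising macro-F1, with accuracy then smaller n as tie-breakers,
    plus the full score table.
    """
    y = np.asarray(true_labels, dtype=int)
    k = np.asarray(prob_matrices[0]).shape[1]
    rows = []
    for stage, grid in (("coarse", coarse), ("fine", fine)):
        for n in grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", NegativeLambdaWarning)
                pred = fuse(prob_matrices, compute_lambdas(f1_list, n))
            rep = aggregate_scores(confusion(y, pred.grades, k))
            rows.append((stage, float(n), rep.accuracy, rep.macro_f1))
    table = pd.DataFrame(rows, columns=["stage", "n", "accuracy", "macro_f1"])
    best = max(
        rows,
        key=lambda r: (round(r[3], 12), round(r[2], 12), -r[1]),
    )
    return NSearchResult(best[1], table)
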