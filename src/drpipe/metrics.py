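"""Multiclass classification metrics for severity grading.

All scores derive from a K x K confusion matrix (rows = true grade,
columns = predicted grade) via one-vs-rest counts:

* per-class precision ``TP/(TP+FP)``, recall ``TP/(TP+FN)``, specificity
  ``TN/(FP+TN)`` and F1 (harmonic mean of precision and recall);
* ACA — the mean of the row-normalised diagonal (balanced accuracy);
* macro-F1 — unweighted mean of per-class F1;
* micro-F1 — F1 of the globally pooled one-vs-rest counts, which for
  single-label multiclass equals plain accuracy;
* one-vs-rest AUC by the rank-sum (Mann-Whitney) formulation with midrank
  ties, macro-averaged over classes.

Ratios with vanishing denominators are defined as 0 (conservative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateClass, EmptyClass, LengthMismatch

__all__ = [
    "MetricsReport",
    "confusion",
    "per_class_scores",
    "aggregate_scores",
    "auc_ovr",
    "auc_per_class",
    "f1_from_precision_recall",
    "report",
]


def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    """Elementwise num/den with 0/0 (and x/0) defined as 0."""
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    out = np.zeros(np.broadcast(num, den).shape)
    np.divide(num, den, out=out, where=den != 0)
    return out


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def confusion(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count (true, predicted) pairs into an ``n_classes**2`` matrix.

    Raises
    ------
    LengthMismatch
        If the label vectors differ in length.
    """
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise LengthMismatch(f"label vectors disagree: {yt.shape} vs {yp.shape}")
    if yt.size and (min(yt.min(), yp.min()) < 0 or max(yt.max(), yp.max()) >= n_classes):
        raise ValueError(f"labels must lie in [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (yt, yp), 1)
    return cm


def _ovr_counts(cm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One-vs-rest (TP, FP, FN, TN) per class from a confusion matrix."""
    cm = np.asarray(cm)
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    tn = cm.sum() - tp - fp - fn
    return tp, fp, fn, tn


@dataclass
class MetricsReport:
    """Per-class and aggregate scores for a K-grade classifier."""

    n_classes: int
    support: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    specificity: np.ndarray
    f1: np.ndarray
    accuracy: float
    macro_f1: float = float("nan")
    micro_f1: float = float("nan")
    aca: float = float("nan")
    auc: float | None = None
    auc_classwise: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        """Tabular layout: one metric per row, one class per column plus
        an Overall column.

        The per-class "Accuracy" row repeats recall (the conventional
        per-class accuracy in grading reports); Overall precision/recall/
        F1/specificity are support-weighted means, Overall accuracy is the
        global accuracy and Overall AUC the macro average.
        """
        cols = [str(c) for c in range(self.n_classes)] + ["Overall"]
        w = _safe_div(self.support, self.support.sum())

        def row(values: np.ndarray, overall: float) -> list[float]:
            return [*(round(float(v), 4) for v in values), round(float(overall), 4)]

        data = {
            "Precision": row(self.precision, float(self.precision @ w)),
            "Recall": row(self.recall, float(self.recall @ w)),
            "F1": row(self.f1, float(self.f1 @ w)),
            "Specificity": row(self.specificity, float(self.specificity @ w)),
            "Accuracy": row(self.recall, self.accuracy),
        }
        if self.auc_classwise is not None and self.auc is not None:
            data["AUC"] = row(self.auc_classwise, self.auc)
        data["Support"] = [*(int(s) for s in self.support), int(self.support.sum())]
        return pd.DataFrame.from_dict(data, orient="index", columns=cols)

    def to_text(self) -> str:
        lines = [self.to_frame().to_string()]
        lines.append("")
        lines.append(
            f"ACA={self.aca:.4f}  Macro-F1={self.macro_f1:.4f}  "
            f"Micro-F1={self.micro_f1:.4f}  Accuracy={self.accuracy:.4f}"
        )
        return "\n".join(lines)


def per_class_scores(cm: np.ndarray) -> MetricsReport:
    """Per-class precision/recall/specificity/F1 plus global accuracy."""
    cm = np.asarray(cm)
    tp, fp, fn, tn = _ovr_counts(cm)
    precision = _safe_div(tp, tp + fp)
    recall = _safe_div(tp, tp + fn)
    specificity = _safe_div(tn, fp + tn)
    f1 = _safe_div(2 * precision * recall, precision + recall)
    total = cm.sum()
    accuracy = float(np.trace(cm) / total) if total else 0.0
    return MetricsReport(
        n_classes=cm.shape[0],
        support=cm.sum(axis=1),
        precision=precision,
        recall=recall,
        specificity=specificity,
        f1=f1,
        accuracy=accuracy,
    )


def aggregate_scores(cm: np.ndarray) -> MetricsReport:
    """Per-class scores plus ACA, macro-F1 and micro-F1.

    Raises
    ------
    EmptyClass
        If some true class has zero samples (row sum 0), making the
        row-normalised diagonal — hence ACA — undefined.
    """
    cm = np.asarray(cm)
    rep = per_class_scores(cm)
    row_sums = cm.sum(axis=1)
    if np.any(row_sums == 0):
        raise EmptyClass(f"true classes with no samples: {np.flatnonzero(row_sums == 0).tolist()}")
    rep.aca = float(np.mean(np.diag(cm) / row_sums))
    rep.macro_f1 = float(rep.f1.mean())
    tp, fp, fn, _ = _ovr_counts(cm)
    rep.micro_f1 = float(_safe_div(tp.sum(), tp.sum() + 0.5 * (fp.sum() + fn.sum())))
    return rep


def auc_per_class(y_true, probabilities) -> np.ndarray:
    """One-vs-rest ranking AUC per class, midrank ties.

    For class c, AUC is the probability that a random positive sample
    receives a higher class-c score than a random negative one (ties
    counting half), computed by the rank-sum identity.

    Raises
    ------
    DegenerateClass
        If some class has no positive or no negative samples.
    """
    yt = np.asarray(y_true, dtype=int)
    probs = np.asarray(probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[0] != yt.size:
        raise LengthMismatch(f"probabilities {probs.shape} do not align with {yt.size} labels")
    aucs = np.empty(probs.shape[1])
    for c in range(probs.shape[1]):
        pos = yt == c
        n_pos = int(pos.sum())
        n_neg = yt.size - n_pos
        if n_pos == 0 or n_neg == 0:
            raise DegenerateClass(f"class {c} has {n_pos} positives and {n_neg} negatives")
        ranks = rankdata(probs[:, c])
        aucs[c] = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return aucs


def auc_ovr(y_true, probabilities) -> float:
    """Macro-averaged one-vs-rest AUC."""
    return float(auc_per_class(y_true, probabilities).mean())


def report(y_true, y_pred, probabilities=None, n_classes: int = 5) -> MetricsReport:
    """Full report from labels (and optionally probabilities, for AUC)."""
    cm = confusion(y_true, y_pred, n_classes)
    rep = aggregate_scores(cm)
    if probabilities is not None:
        rep.auc_classwise = auc_per_class(y_true, probabilities)
        rep.auc = float(rep.auc_classwise.mean())
    return rep
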