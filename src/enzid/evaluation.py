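"""Confusion-matrix metrics and ROC/AUC analysis for the binary classifier.

The ACC/SP/SE definitions follow the published human-enzyme study convention,
which names SP = TP/(TP+FN) and SE = TN/(TN+FP) — the *reverse* of standard
usage, where TP/(TP+FN) is the sensitivity.  Both namings are exposed: the
``sp_paper``/``se_paper`` fields reproduce the study's tables verbatim, and
``sensitivity_std``/``specificity_std`` carry the same numbers under their
standard names.  ACC is reported as a percentage in [0, 100].

Ratios with a zero denominator are reported as NaN with a warning, never
coerced to 0 or 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionMatrix",
    "MetricSet",
    "ROCCurve",
    "confusion",
    "metrics",
    "roc_auc",
    "pool_confusions",
    "plot_roc",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """TP/TN/FP/FN counts; positive class = enzyme."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionMatrix") -> "ConfusionMatrix":
        return ConfusionMatrix(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricSet:
    """ACC (percent) and the two class-conditional rates, in both namings."""

    acc: float
    sp_paper: float  # TP/(TP+FN): rate on positives
    se_paper: float  # TN/(TN+FP): rate on negatives

    @property
    def sensitivity_std(self) -> float:
        """Standard sensitivity (true-positive rate); alias of ``sp_paper``."""
        return self.sp_paper

    @property
    def specificity_std(self) -> float:
        """Standard specificity (true-negative rate); alias of ``se_paper``."""
        return self.se_paper

    def to_dict(self) -> dict:
        return {
            "acc_percent": self.acc,
            "sp_paper": self.sp_paper,
            "se_paper": self.se_paper,
            "sensitivity_std": self.sensitivity_std,
            "specificity_std": self.specificity_std,
        }


@dataclass(frozen=True)
class ROCCurve:
    """Threshold-swept ROC points and trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.fpr.tolist(), self.tpr.tolist()))


def confusion(
    true_labels: Sequence[int], predicted_labels: Sequence[int], positive: int = 1
) -> ConfusionMatrix:
    """Cross-classify true vs predicted labels into TP/TN/FP/FN."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError(f"label length mismatch: {y.shape} vs {p.shape}")
    pos_t, pos_p = y == positive, p == positive
    return ConfusionMatrix(
        tp=int(np.sum(pos_t & pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
    )


def pool_confusions(folds: Iterable[ConfusionMatrix]) -> ConfusionMatrix:
    """Elementwise sum of per-fold confusion matrices."""
    total = ConfusionMatrix(0, 0, 0, 0)
    for cm in folds:
        total = total + cm
    return total


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def metrics(cm: ConfusionMatrix) -> MetricSet:
    """ACC = (TP+TN)/total * 100%; SP = TP/(TP+FN); SE = TN/(TN+FP)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.total * 100.0
    sp = _safe_ratio(cm.tp, cm.tp + cm.fn, "SP = TP/(TP+FN)")
    se = _safe_ratio(cm.tn, cm.tn + cm.fp, "SE = TN/(TN+FP)")
    return MetricSet(acc=acc, sp_paper=sp, se_paper=se)


def roc_auc(
    true_labels: Sequence[int], decision_scores: Sequence[float], positive: int = 1
) -> ROCCurve:
    """ROC by descending-threshold sweep (ties grouped), AUC by trapezoid.

    The curve starts at (0, 0) and ends at (1, 1); tied scores advance the
    curve diagonally in a single step.
    """
    y = np.asarray(true_labels)
    s = np.asarray(decision_scores, dtype=float)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("ROC requires both classes present")
    fpr, tpr, thr = _sk_roc_curve(y == positive, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc)


def plot_roc(
    curve: ROCCurve, path: Union[str, Path], title: Optional[str] = None
) -> None:
    """Save a ROC plot (PNG/PDF by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(curve.fpr, curve.tpr, lw=1.5, label=f"AUC = {curve.auc:.4f}")
    ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.set_title(title or "ROC")
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
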