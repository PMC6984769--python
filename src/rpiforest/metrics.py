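"""Binary-classifier evaluation: confusion-matrix metrics and ROC/AUC.

The five reported indices are

    Sens = TP/(TP+FN)            Spec = TN/(TN+FP)
    ACC  = (TP+TN)/total
    MCC  = (TP*TN - FP*FN) / sqrt((TP+FN)(TP+FP)(TN+FP)(TN+FN))
    AUC  = P(score_pos > score_neg), ties counted half

MCC is returned as 0 (with a warning) when any denominator factor
vanishes — the classifier is uninformative there and the formula is
undefined.  AUC uses the rank (Mann-Whitney) formulation, which is
well-defined under tied scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from math import sqrt
from typing import Optional

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve


@dataclass(frozen=True)
class ConfusionCounts:
    """True/false positive/negative counts of a binary classifier."""

    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts are all zero")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.TP + other.TP, self.FP + other.FP,
                               self.TN + other.TN, self.FN + other.FN)


@dataclass(frozen=True)
class MetricsReport:
    """Sens, Spec, ACC, MCC and (optionally) AUC."""

    Sens: float
    Spec: float
    ACC: float
    MCC: float
    AUC: Optional[float] = None

    def as_dict(self) -> dict:
        return asdict(self)


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    """Tally TP/FP/TN/FN from 0/1 label and prediction vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def compute_metrics(c: ConfusionCounts, auc_value: Optional[float] = None
                    ) -> MetricsReport:
    """Evaluate Sens/Spec/ACC/MCC from counts; Sens (Spec) is 0 when the
    positive (negative) class is absent."""
    sens = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    spec = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    acc = (c.TP + c.TN) / c.total
    denom = (c.TP + c.FN) * (c.TP + c.FP) * (c.TN + c.FP) * (c.TN + c.FN)
    if denom == 0:
        warnings.warn("MCC denominator is zero; reporting MCC = 0",
                      RuntimeWarning, stacklevel=2)
        mcc = 0.0
    else:
        mcc = (c.TP * c.TN - c.FP * c.FN) / sqrt(denom)
    return MetricsReport(Sens=sens, Spec=spec, ACC=acc, MCC=mcc, AUC=auc_value)


def _check_both_classes(labels: np.ndarray) -> None:
    if not (np.any(labels == 1) and np.any(labels == 0)):
        raise ValueError("both classes must be present to compute ROC/AUC")


def auc(scores, labels) -> float:
    """Area under the ROC curve by the rank statistic (ties count half)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_both_classes(labels)
    return float(roc_auc_score(labels, scores))


def roc_curve(scores, labels) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points (FPR, TPR, thresholds), monotone from (0,0) to (1,1)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_both_classes(labels)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return fpr, tpr, thr
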