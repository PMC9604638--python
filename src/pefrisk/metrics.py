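"""Confusion-matrix metrics, ROC AUC and relative-improvement arithmetic.

Metrics follow the standard clinical-classifier definitions: sensitivity
(recall on the risk class), specificity, precision, F1 and the *weighted
accuracy* (sensitivity + specificity) / 2, i.e. balanced accuracy.  A
denominator of zero marks the metric ``undefined`` (None) rather than
propagating NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_from_predictions",
    "compute_metrics",
    "roc_auc",
    "relative_improvement",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts; the positive class is the risk class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"confusion count {name} must be >= 0")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricsReport:
    """Per-model metric set; ``None`` marks an undefined (0/0) metric."""

    weighted_accuracy: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    precision: Optional[float]
    f1: Optional[float]
    roc_auc: Optional[float] = None

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ConfusionMatrix:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionMatrix(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
    )


def compute_metrics(
    cm: ConfusionMatrix, *, literal_specificity: bool = False
) -> MetricsReport:
    """Compute the metric set from a confusion matrix.

    Parameters
    ----------
    cm
        Confusion counts with the risk class positive.
    literal_specificity
        The conventional specificity is TN / (TN + FP).  Some reports print
        the variant TN / (FP + FN); set this flag to reproduce that variant
        for auditing.  The default keeps the identity
        ``weighted_accuracy == (sensitivity + specificity) / 2``.
    """
    if cm.n < 1:
        raise ValueError("empty confusion matrix")
    sens = _ratio(cm.tp, cm.tp + cm.fn)
    if literal_specificity:
        spec = _ratio(cm.tn, cm.fp + cm.fn)
    else:
        spec = _ratio(cm.tn, cm.tn + cm.fp)
    prec = _ratio(cm.tp, cm.tp + cm.fp)
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        f1 = None
    # weighted accuracy = TP/(2(TP+FN)) + TN/(2(TN+FP))
    conv_spec = _ratio(cm.tn, cm.tn + cm.fp)
    if sens is not None and conv_spec is not None:
        wacc = 0.5 * (sens + conv_spec)
    else:
        wacc = None
    return MetricsReport(
        weighted_accuracy=wacc,
        sensitivity=sens,
        specificity=spec,
        precision=prec,
        f1=f1,
    )


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], *, method: str = "rank"
) -> Optional[float]:
    """Area under the ROC curve as the Mann–Whitney probability.

    AUC = P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg),
    computed either by the midrank formula (``method="rank"``) or by
    explicit pairwise comparison (``method="pairwise"``).  Returns ``None``
    when only one class is present.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    if method == "rank":
        r = rankdata(s)  # midranks handle ties
        auc = (np.sum(r[y == 1]) - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    elif method == "pairwise":
        pos = s[y == 1][:, None]
        neg = s[y == 0][None, :]
        auc = (np.sum(pos > neg) + 0.5 * np.sum(pos == neg)) / (n_pos * n_neg)
    else:
        raise ValueError(f"unknown AUC method {method!r}")
    return float(auc)


def relative_improvement(base: float, improved: float) -> float:
    """Percent gain of ``improved`` over ``base``, to one decimal.

    100 * (improved - base) / base, e.g. (0.614, 0.727) -> 18.4.
    """
    if not math.isfinite(base) or base <= 0:
        raise ValueError("base metric must be positive")
    return round(100.0 * (improved - base) / base, 1)
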