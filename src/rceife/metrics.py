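"""Performance metrics computed from held-out predictions.

All threshold metrics follow the standard confusion-table formulas:

    accuracy    = (TP + TN) / (TP + FP + FN + TN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    precision   = TP / (TP + FP)
    F-measure   = 2 TP / (2 TP + FP + FN)

A metric whose denominator is zero is reported as undefined (``None``),
never coerced to 0 — undefined values are excluded from repetition means.
AUC is the Mann-Whitney probability that a random positive sample outscores
a random negative one (ties counted 1/2), identical to the trapezoidal ROC
area. Cohen's kappa is chance-corrected agreement from the table margins.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.stats import rankdata

from .exceptions import MetricError, ParameterError

__all__ = ["ConfusionCounts", "MetricSet", "confusion_counts",
           "confusion_metrics", "cohen_kappa", "auc"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision",
                "f_measure", "auc", "kappa")


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion table (positive = the 'pos' label)."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.fp, self.tn, self.fn)
        if any(c < 0 for c in counts):
            raise ParameterError("confusion counts must be non-negative")
        if sum(counts) < 1:
            raise ParameterError("confusion table must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """The full per-level metric readout; ``None`` marks an undefined value."""

    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    precision: float | None = None
    f_measure: float | None = None
    auc: float | None = None
    kappa: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Tally a confusion table from boolean label/prediction vectors."""
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Accuracy, sensitivity, specificity, precision and F-measure."""
    return MetricSet(
        accuracy=_ratio(c.tp + c.tn, c.total),
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        f_measure=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def cohen_kappa(c: ConfusionCounts) -> float | None:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) from the margins."""
    n = c.total
    p_o = (c.tp + c.tn) / n
    # margins: actual pos/neg vs predicted pos/neg
    p_e = ((c.tp + c.fn) * (c.tp + c.fp) + (c.tn + c.fp) * (c.tn + c.fn)) / (n * n)
    if p_e == 1.0:
        return None
    return (p_o - p_e) / (1.0 - p_e)


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of positive-class scores, ties counted 1/2.

    ``labels`` may be a boolean vector or 'pos'/'neg' strings.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    if labels.dtype != bool:
        labels = labels == "pos"
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricError("AUC needs both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    rank_sum_pos = float(ranks[labels].sum())
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)
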