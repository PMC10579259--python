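"""Confusion counts and the five derived percentage metrics.

With true positives (ictal hits) ``tp``, true negatives ``tn``, false
positives ``fp`` and false negatives ``fn``:

* accuracy   = (tp + tn) / total x 100
* sensitivity = tp / (tp + fn) x 100
* specificity = tn / (tn + fp) x 100
* precision   = tp / (tp + fp) x 100
* F1 score    = 2 * Pr * Se / (Pr + Se) x 100  (Pr, Se as fractions)

A metric whose denominator is zero is reported as 0 with a warning so
that fold aggregation always stays total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "MetricsRecord", "compute_metrics",
           "threshold_predictions"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts for one evaluated batch of segments."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsRecord:
    """The five derived metrics, as percentages in [0, 100]."""

    acc: float
    se: float
    sp: float
    pr: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return {"Se": self.se, "Sp": self.sp, "Acc": self.acc,
                "Pr": self.pr, "F1": self.f1}


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting 0",
                      RuntimeWarning, stacklevel=3)
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts) -> MetricsRecord:
    """Derive accuracy, sensitivity, specificity, precision and F1."""
    if counts.total == 0:
        raise ValueError("no evaluated segments")
    acc = (counts.tp + counts.tn) / counts.total
    se = _ratio(counts.tp, counts.tp + counts.fn, "sensitivity")
    sp = _ratio(counts.tn, counts.tn + counts.fp, "specificity")
    pr = _ratio(counts.tp, counts.tp + counts.fp, "precision")
    f1 = 2.0 * pr * se / (pr + se) if (pr + se) > 0 else 0.0
    return MetricsRecord(acc=100.0 * acc, se=100.0 * se, sp=100.0 * sp,
                         pr=100.0 * pr, f1=100.0 * f1)


def threshold_predictions(probabilities: np.ndarray, labels: np.ndarray,
                          tau: float = 0.5
                          ) -> tuple[np.ndarray, ConfusionCounts]:
    """Binarize probabilities at ``tau`` (ties go to class 1) and tally.

    Returns the predicted labels and the confusion counts against the
    ground truth; counts always sum to the batch size.
    """
    p = np.asarray(probabilities)
    x = np.asarray(labels).astype(bool)
    if p.shape != x.shape:
        raise ValueError("probabilities and labels must align")
    pred = p >= tau
    return pred.astype(np.int8), ConfusionCounts(
        tp=int(np.sum(pred & x)),
        tn=int(np.sum(~pred & ~x)),
        fp=int(np.sum(pred & ~x)),
        fn=int(np.sum(~pred & x)),
    )
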