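"""Confusion-matrix measures, the log-likelihood-ratio cost, and the
ENFSI verbal scale.

Cllr is the strictly proper scoring rule used throughout forensic evidence
evaluation:

    Cllr = 1/2 [ 1/N1 * sum_i log2(1 + 1/LR1_i) + 1/N2 * sum_j log2(1 + LR2_j) ]

where LR1 are likelihood ratios for truly-positive items and LR2 for
truly-negative ones.  A system that always answers LR = 1 scores exactly 1
("useless but calibrated"); perfect evidence drives it to 0.  The log base
defaults to 2 (the convention of the forensic comparison literature) and is
exposed as a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .exceptions import InvalidConfigError, ShapeError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "LRResult",
    "confusion_matrix",
    "classification_metrics",
    "cllr",
    "saturate_lrs",
    "verbal_scale",
    "LR_SATURATION",
]

LR_SATURATION = 1e300

METRIC_NAMES = ("precision", "recall", "specificity", "accuracy", "error", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise InvalidConfigError("confusion counts must be nonnegative")
        if self.total < 1:
            raise InvalidConfigError("confusion matrix must count at least one item")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def n_positive(self) -> int:  # N+
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:  # N-
        return self.fp + self.tn

    @property
    def n_predicted_positive(self) -> int:  # N^+
        return self.tp + self.fp

    @property
    def n_predicted_negative(self) -> int:  # N^-
        return self.fn + self.tn


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-derived measures; None marks a 0/0-undefined value."""

    precision: Optional[float]
    recall: Optional[float]
    specificity: Optional[float]
    accuracy: float
    error: float
    f1: Optional[float]
    cllr: Optional[float] = None

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "error": self.error,
            "f1": self.f1,
            "cllr": self.cllr,
        }


@dataclass(frozen=True)
class LRResult:
    """One item's evidential result: LR, posterior, class, verbal label."""

    lr: float
    log10_lr: float
    posterior_p: float
    predicted_class: str
    verbal: str
    saturated: bool = False


def confusion_matrix(truth, predicted, positive=1) -> ConfusionMatrix:
    """Count TP/FP/FN/TN from paired label vectors."""
    t = np.asarray(truth)
    p = np.asarray(predicted)
    if t.shape != p.shape or t.ndim != 1 or t.size < 1:
        raise ShapeError("truth and predicted must be equal-length vectors")
    tpos = t == positive
    ppos = p == positive
    return ConfusionMatrix(
        tp=int(np.sum(tpos & ppos)),
        fp=int(np.sum(~tpos & ppos)),
        fn=int(np.sum(tpos & ~ppos)),
        tn=int(np.sum(~tpos & ~ppos)),
    )


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def classification_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Precision, recall, specificity, accuracy, error and F1.

    Zero-denominator cases (e.g. no predicted positives) yield None and are
    excluded from downstream averages with a logged count.
    """
    precision = _ratio(cm.tp, cm.n_predicted_positive)
    recall = _ratio(cm.tp, cm.n_positive)
    specificity = _ratio(cm.tn, cm.n_negative)
    accuracy = (cm.tp + cm.tn) / cm.total
    error = (cm.fp + cm.fn) / cm.total
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2.0 * recall * precision / (recall + precision)
    return MetricsReport(
        precision=precision,
        recall=recall,
        specificity=specificity,
        accuracy=accuracy,
        error=error,
        f1=f1,
    )


def saturate_lrs(lrs) -> tuple[np.ndarray, int]:
    """Clip LRs into [1/LR_SATURATION, LR_SATURATION]; count clips."""
    lrs = np.asarray(lrs, dtype=float)
    clipped = np.clip(lrs, 1.0 / LR_SATURATION, LR_SATURATION)
    return clipped, int(np.sum(clipped != lrs))


def cllr(lr_pos, lr_neg, base: float = 2.0) -> float:
    """Log-likelihood-ratio cost of a set of LRs (see module docstring)."""
    lr_pos = np.asarray(lr_pos, dtype=float)
    lr_neg = np.asarray(lr_neg, dtype=float)
    if lr_pos.size < 1 or lr_neg.size < 1:
        raise InvalidConfigError("both LR vectors must be nonempty")
    if (lr_pos <= 0).any() or (lr_neg <= 0).any():
        raise InvalidConfigError("LRs must be strictly positive (floor upstream)")
    log_base = np.log(base)
    term_pos = np.mean(np.log1p(1.0 / lr_pos)) / log_base
    term_neg = np.mean(np.log1p(lr_neg)) / log_base
    return 0.5 * (term_pos + term_neg)


_VERBAL_BINS = (
    (1e1, "weak"),
    (1e2, "moderate"),
    (1e3, "moderately strong"),
    (1e4, "strong"),
    (1e5, "very strong"),
)


def verbal_scale(lr: float) -> str:
    """Decade-based ENFSI verbal label for an LR.

    1 < LR <= 10 gives weak support for H1, each further decade one step up
    to 'extremely strong' beyond 1e5; LR = 1 is inconclusive; LR < 1 maps
    through 1/LR onto the mirrored H2 bins.
    """
    if lr <= 0:
        raise InvalidConfigError("LR must be strictly positive")
    if lr == 1.0:
        return "inconclusive"
    hypothesis = "H1" if lr > 1.0 else "H2"
    mag = lr if lr > 1.0 else 1.0 / lr
    for edge, label in _VERBAL_BINS:
        if mag <= edge:
            return f"{label} support for {hypothesis}"
    return f"extremely strong support for {hypothesis}"
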