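"""Gaussian discriminant baselines (LDA/QDA) with LR-style outputs.

Both model each class as a multivariate Gaussian; LDA pools one covariance
across classes (linear boundary, log-LR linear in x), QDA keeps per-class
covariances (quadratic boundary).  The reported LR is the pure
class-conditional density ratio — class priors are kept out of it and
reported separately, so the LR is comparable with the fusion methods'.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import multivariate_normal

from .datasets import LabeledDataset
from .exceptions import DegenerateDataError, InvalidConfigError, ShapeError
from .fusion import lr_results_from_log_lr
from .metrics import LRResult

__all__ = ["DiscriminantModel", "fit_discriminant", "predict_discriminant"]

logger = logging.getLogger(__name__)


@dataclass
class DiscriminantModel:
    kind: str  # "lda" | "qda"
    mean_pos: np.ndarray
    mean_neg: np.ndarray
    cov_pos: np.ndarray  # equals cov_neg (pooled) for lda
    cov_neg: np.ndarray
    prior_pos: float
    prior_neg: float
    positive_label: str = "positive"
    negative_label: str = "negative"

    @property
    def prior_odds(self) -> float:
        return self.prior_pos / self.prior_neg


def _regularize(cov: np.ndarray, k: int) -> np.ndarray:
    """Ridge jitter (1e-8 * trace / k on the diagonal) until PD."""
    jitter = 1e-8 * np.trace(cov) / max(k, 1)
    if jitter <= 0:
        jitter = 1e-8
    for attempt in range(8):
        try:
            np.linalg.cholesky(cov)
            return cov
        except np.linalg.LinAlgError:
            logger.info("covariance singular; adding jitter %.3g", jitter)
            cov = cov + jitter * np.eye(k)
            jitter *= 10.0
    raise DegenerateDataError("covariance matrix is singular beyond repair")


def fit_discriminant(
    data: LabeledDataset, kind: str = "lda", equal_priors: bool = False
) -> DiscriminantModel:
    """Fit Gaussian class-conditionals with empirical (or equal) priors."""
    if kind not in {"lda", "qda"}:
        raise InvalidConfigError(f"unknown discriminant kind {kind!r}")
    data.require_both_classes()
    X, y = data.features, data.labels
    k = data.k
    Xp, Xn = X[y == 1], X[y == 0]
    if kind == "qda" and (len(Xp) < k + 1 or len(Xn) < k + 1):
        raise DegenerateDataError("qda needs at least k+1 rows per class")
    if kind == "lda" and data.n < k + 2:
        raise DegenerateDataError("lda needs at least k+2 rows")

    mp, mn = Xp.mean(axis=0), Xn.mean(axis=0)
    if kind == "lda":
        Sp = np.atleast_2d(np.cov(Xp, rowvar=False))
        Sn = np.atleast_2d(np.cov(Xn, rowvar=False))
        pooled = ((len(Xp) - 1) * Sp + (len(Xn) - 1) * Sn) / (data.n - 2)
        pooled = _regularize(pooled, k)
        cov_p = cov_n = pooled
    else:
        cov_p = _regularize(np.atleast_2d(np.cov(Xp, rowvar=False)), k)
        cov_n = _regularize(np.atleast_2d(np.cov(Xn, rowvar=False)), k)

    if equal_priors:
        prior_pos = prior_neg = 0.5
    else:
        prior_pos = len(Xp) / data.n
        prior_neg = len(Xn) / data.n
    return DiscriminantModel(
        kind=kind,
        mean_pos=mp,
        mean_neg=mn,
        cov_pos=cov_p,
        cov_neg=cov_n,
        prior_pos=prior_pos,
        prior_neg=prior_neg,
        positive_label=data.positive_label,
        negative_label=data.negative_label,
    )


def discriminant_log_lr(model: DiscriminantModel, features: np.ndarray) -> np.ndarray:
    """log f(x|pos) - log f(x|neg): priors excluded by construction."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.mean_pos.size:
        raise ShapeError(
            f"expected {model.mean_pos.size} columns, got {X.shape[1]}"
        )
    lp = multivariate_normal.logpdf(X, mean=model.mean_pos, cov=model.cov_pos)
    ln = multivariate_normal.logpdf(X, mean=model.mean_neg, cov=model.cov_neg)
    return np.atleast_1d(lp - ln)


def predict_discriminant(
    model: DiscriminantModel,
    features: np.ndarray,
    threshold: float = 0.5,
) -> list[LRResult]:
    """Density-ratio LRs; the class call thresholds the posterior, which
    folds the model's class priors back in."""
    log_lr = discriminant_log_lr(model, features)
    return lr_results_from_log_lr(
        log_lr,
        prior_odds=model.prior_odds,
        threshold=threshold,
        positive_label=model.positive_label,
        negative_label=model.negative_label,
    )
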