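"""Per-variable class-conditional densities and log-LR scores.

A score for variable x is the log ratio of its class-conditional densities,

    s = log f(x | H1) / f(x | H2),

with f estimated either as a Gaussian (sample mean/SD) or by Gaussian-kernel
density estimation,

    fhat(x) = 1/(n h) * sum_i K((x - x_i) / h),

with the bandwidth from Silverman's rule of thumb

    h = 0.9 * min(sigma_hat, IQR / 1.34) * n^(-1/5).

Densities are floored at a tiny positive value before the ratio so scores
stay finite even at extreme extrapolation; scores are natural-log
internally (base-10 conversion happens only at reporting time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import norm

from .exceptions import DegenerateDataError, InvalidConfigError

__all__ = [
    "DensityModel",
    "silverman_bandwidth",
    "silverman_bandwidth_from_summaries",
    "fit_density",
    "density_evaluate",
    "kde_evaluate",
    "score_log_lr",
]

logger = logging.getLogger(__name__)

DENSITY_FLOOR = 1e-300


@dataclass(frozen=True)
class DensityModel:
    """A univariate class-conditional density (Gaussian or Gaussian KDE)."""

    method: str  # "gaussian" | "kde"
    mu: Optional[float] = None
    sigma: Optional[float] = None
    points: Optional[np.ndarray] = None
    bandwidth: Optional[float] = None
    floor: float = DENSITY_FLOOR

    def __post_init__(self) -> None:
        if self.method not in {"gaussian", "kde"}:
            raise InvalidConfigError(f"unknown density method {self.method!r}")
        if self.method == "gaussian" and (self.sigma is None or self.sigma <= 0):
            raise DegenerateDataError("gaussian density requires sigma > 0")
        if self.method == "kde":
            if self.points is None or len(self.points) < 1:
                raise InvalidConfigError("kde density requires training points")
            if self.bandwidth is None or self.bandwidth <= 0:
                raise DegenerateDataError("kde density requires bandwidth > 0")


def silverman_bandwidth_from_summaries(sigma: float, iqr: float, n: int) -> float:
    """Silverman's rule from precomputed spread summaries.

    h = 0.9 * min(sigma, IQR/1.34) * n^(-0.2).  If one spread measure is
    zero the other is used (the min rule is undefined there); both zero is
    degenerate data.
    """
    if n < 1:
        raise InvalidConfigError("n must be positive")
    if sigma <= 0 and iqr <= 0:
        raise DegenerateDataError("constant data: sigma and IQR are both zero")
    if iqr <= 0:
        logger.info("IQR is zero; Silverman rule falling back to sigma alone")
        spread = sigma
    elif sigma <= 0:  # pragma: no cover - sample SD >= IQR-based spread > 0
        spread = iqr / 1.34
    else:
        spread = min(sigma, iqr / 1.34)
    return 0.9 * spread * n ** (-0.2)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth for a sample.

    Uses the sample standard deviation (divisor n-1) and the
    linear-interpolation quartile convention for the IQR; non-finite
    values are dropped first.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InvalidConfigError("need at least 2 finite values")
    sigma = float(np.std(x, ddof=1))
    q1, q3 = np.percentile(x, [25.0, 75.0])  # linear interpolation
    return silverman_bandwidth_from_summaries(sigma, float(q3 - q1), x.size)


def fit_density(x: np.ndarray, method: str = "gaussian") -> DensityModel:
    """Fit a univariate density: Gaussian moments or KDE with Silverman h."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise InvalidConfigError("need at least 2 finite values to fit a density")
    if method == "gaussian":
        sigma = float(np.std(x, ddof=1))
        if sigma <= 0:
            raise DegenerateDataError("constant data: Gaussian sigma is zero")
        return DensityModel(method="gaussian", mu=float(np.mean(x)), sigma=sigma)
    if method == "kde":
        h = silverman_bandwidth(x)
        return DensityModel(method="kde", points=x.copy(), bandwidth=h)
    raise InvalidConfigError(f"unknown density method {method!r}")


def kde_evaluate(model: DensityModel, x) -> np.ndarray | float:
    """fhat(x) = 1/(n h) sum_i K((x - x_i)/h) with a Gaussian kernel."""
    if model.method != "kde":
        raise InvalidConfigError("kde_evaluate requires a kde DensityModel")
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    u = (xv[:, None] - model.points[None, :]) / model.bandwidth
    dens = norm.pdf(u).mean(axis=1) / model.bandwidth
    dens = np.maximum(dens, model.floor)
    return dens if np.ndim(x) else float(dens[0])


def density_evaluate(model: DensityModel, x) -> np.ndarray | float:
    """Evaluate either density type, floored at ``model.floor``."""
    if model.method == "kde":
        return kde_evaluate(model, x)
    xv = np.atleast_1d(np.asarray(x, dtype=float))
    dens = norm.pdf(xv, loc=model.mu, scale=model.sigma)
    dens = np.maximum(dens, model.floor)
    return dens if np.ndim(x) else float(dens[0])


def score_log_lr(x, pos_model: DensityModel, neg_model: DensityModel):
    """Natural-log LR score: log f(x|H1) - log f(x|H2), always finite.

    Mixing density methods between the classes is allowed (and logged).
    """
    if pos_model.method != neg_model.method:
        logger.info(
            "mixing density methods: pos=%s neg=%s", pos_model.method, neg_model.method
        )
    fp = density_evaluate(pos_model, x)
    fn = density_evaluate(neg_model, x)
    return np.log(fp) - np.log(fn)
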