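"""Unpenalized binary logistic regression with separation diagnostics.

The model is the usual logit link,

    logit(p) = b0 + b1*x1 + ... + bk*xk,

fitted by Newton/IRLS with step-halving.  Under perfect separation the
maximum-likelihood estimate does not exist (coefficients diverge and
standard errors blow up by orders of magnitude); this module both exhibits
that symptom honestly and *decides* separation exactly with a linear
program, independently of any fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np
from scipy.optimize import linprog
from scipy.special import expit

from .datasets import LabeledDataset
from .exceptions import CollinearityError, InvalidConfigError, ShapeError

__all__ = [
    "FittedGLM",
    "SeparationReport",
    "LRValue",
    "fit_logistic_mle",
    "predict_prob",
    "posterior_to_lr",
    "detect_separation",
    "log_likelihood",
]

logger = logging.getLogger(__name__)

# probabilities are clamped only inside likelihood evaluation, never in
# reported outputs
_P_CLAMP = 1e-15
# SE/|coef| ratio beyond which we report the classic separation symptom
SE_RATIO_SYMPTOM = 1e3


@dataclass
class FittedGLM:
    """A fitted (possibly penalized) binary logistic model.

    ``coefficients`` are always reported on the original variable scale,
    intercept first; ``scale_info`` records any internal centering/scaling.
    """

    method: str
    coefficients: np.ndarray
    std_errors: Optional[np.ndarray] = None
    converged: bool = True
    separation_flag: bool = False
    n_iter: int = 0
    penalty: Optional[object] = None
    scale_info: Optional[dict] = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]

    def se_coef_ratios(self) -> Optional[np.ndarray]:
        """|SE| / |coefficient| — huge values are a separation symptom."""
        if self.std_errors is None:
            return None
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.abs(self.std_errors) / np.abs(self.coefficients)


@dataclass
class SeparationReport:
    separated: bool
    quasi_separated: bool
    witness: Optional[dict] = None
    se_coef_ratios: Optional[np.ndarray] = None


class LRValue(NamedTuple):
    lr: float
    saturated: bool


def _design(X: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0]), X])


def log_likelihood(beta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    """Binomial log-likelihood at ``beta`` (intercept first), clamped p."""
    eta = _design(X) @ beta
    # y*eta - log(1 + e^eta), overflow-safe
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_mle(
    data: LabeledDataset, max_iter: int = 100, tol: float = 1e-8
) -> FittedGLM:
    """Maximum-likelihood fit by Newton/IRLS with step-halving.

    On separated data the likelihood has no interior maximum: the fit stops
    at the iteration cap, ``converged`` is False and/or ``separation_flag``
    is True, and the returned coefficients are flagged unreliable (their
    standard errors dwarf them, mirroring the textbook symptom).
    """
    data.require_both_classes()
    X, y = data.features, data.labels.astype(float)
    if not np.isfinite(X).all():
        raise InvalidConfigError("features contain missing/non-finite values")
    Xd = _design(X)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise CollinearityError(
            "design matrix is rank-deficient (constant or collinear column)"
        )

    beta = np.zeros(Xd.shape[1])
    ll = log_likelihood(beta, X, y)
    ll_path = [ll]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = expit(Xd @ beta)
        grad = Xd.T @ (y - p)
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        w = np.clip(p * (1.0 - p), _P_CLAMP, None)
        info = Xd.T @ (Xd * w[:, None])
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving keeps the log-likelihood non-decreasing
        t = 1.0
        for _ in range(50):
            ll_new = log_likelihood(beta + t * step, X, y)
            # tolerance absorbs float noise at the optimum
            if ll_new >= ll - 1e-10 * (1.0 + abs(ll)):
                break
            t *= 0.5
        beta = beta + t * step
        ll = ll_new
        ll_path.append(ll)
    else:
        it = max_iter

    p = expit(Xd @ beta)
    w = np.clip(p * (1.0 - p), _P_CLAMP, None)
    info = Xd.T @ (Xd * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(beta.shape, np.inf)

    sep = detect_separation(data)
    fit = FittedGLM(
        method="mle",
        coefficients=beta,
        std_errors=se,
        converged=converged and not sep.separated,
        separation_flag=sep.separated or sep.quasi_separated,
        n_iter=it,
        diagnostics={
            "loglik_path": np.array(ll_path),
            "final_gradient_max": float(np.max(np.abs(Xd.T @ (y - p)))),
            "fitted_probabilities": p,
        },
    )
    sep.se_coef_ratios = fit.se_coef_ratios()
    fit.diagnostics["separation_report"] = sep
    if fit.separation_flag:
        logger.warning(
            "perfect/quasi separation detected: MLE coefficients unreliable"
        )
    return fit


def predict_prob(fit: FittedGLM, features: np.ndarray) -> np.ndarray:
    """P(positive) per row via the overflow-safe logistic transform."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != fit.coefficients.size - 1:
        raise ShapeError(
            f"expected {fit.coefficients.size - 1} columns, got {X.shape[1]}"
        )
    return expit(_design(X) @ fit.coefficients)


def posterior_to_lr(p: float, prior_odds: float = 1.0) -> LRValue:
    """Convert a posterior probability to a likelihood ratio.

    Posterior odds = prior odds x LR, so LR = (p/(1-p)) / prior_odds.  With
    the conventional prior odds of 1 the LR is simply the posterior odds.
    Saturated inputs (p exactly 0 or 1) return 0 or +inf with a flag.
    """
    if prior_odds <= 0:
        raise InvalidConfigError("prior_odds must be positive")
    if not 0.0 <= p <= 1.0:
        raise InvalidConfigError("p must lie in [0, 1]")
    if p == 0.0:
        return LRValue(0.0, True)
    if p == 1.0:
        return LRValue(np.inf, True)
    return LRValue((p / (1.0 - p)) / prior_odds, False)


def detect_separation(data: LabeledDataset, tol: float = 1e-7) -> SeparationReport:
    """Exact separation check by linear feasibility (no model fitting).

    Searches for a direction (w, c) with z_i (w.x_i + c) >= 0 for all rows
    (z = +/-1 class signs).  One LP maximizes sum_i min(margin_i, 1):
    an optimum of n means every margin can reach 1, i.e. *complete*
    separation (strict inequalities exist after rescaling); a positive
    optimum below n means quasi-separation (boundary rows remain); an
    optimum of 0 means genuine overlap in every direction.
    """
    data.require_both_classes()
    X = data.features
    n, k = X.shape
    z = np.where(data.labels == 1, 1.0, -1.0)

    # standardize for LP conditioning; witness mapped back afterwards
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    S = z[:, None] * Xs  # margins are S @ w + z*c

    # variables: w (k), c (1), t (n); maximize sum t
    n_var = k + 1 + n
    c_obj = np.zeros(n_var)
    c_obj[k + 1 :] = -1.0
    # t_i - (S w + z c)_i <= 0
    A1 = np.hstack([-S, -z[:, None], np.eye(n)])
    # -(S w + z c)_i <= 0
    A2 = np.hstack([-S, -z[:, None], np.zeros((n, n))])
    A = np.vstack([A1, A2])
    b = np.zeros(2 * n)
    # w, c free: any strictly positive margin can be rescaled to reach 1,
    # so the optimum counts the rows that can sit strictly off the boundary
    bounds = [(None, None)] * (k + 1) + [(0.0, 1.0)] * n
    res = linprog(c_obj, A_ub=A, b_ub=b, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS handles these LPs
        raise RuntimeError(f"separation LP failed: {res.message}")
    opt = -res.fun
    separated = opt >= n - 0.5
    quasi = (opt > max(0.5, n * tol)) and not separated

    witness = None
    if separated or quasi:
        # prefer the most interpretable witness: single variables that
        # separate on their own (the marginal-gap check is exact)
        singles = []
        if separated:
            for j in range(k):
                pos, neg = X[data.labels == 1, j], X[data.labels == 0, j]
                if pos.min() > neg.max() or neg.min() > pos.max():
                    singles.append(j)
        if singles:
            j = singles[0]
            pos, neg = X[data.labels == 1, j], X[data.labels == 0, j]
            sign = 1.0 if pos.min() > neg.max() else -1.0
            w = np.zeros(k)
            w[j] = sign
            thresh = (
                (pos.min() + neg.max()) / 2
                if sign > 0
                else (pos.max() + neg.min()) / 2
            )
            witness = {
                "direction": w,
                "intercept": -sign * thresh,
                "variables": [data.variable_names[j] for j in singles],
            }
        else:
            w_s, c_s = res.x[:k], res.x[k]
            w = w_s / sd
            c = c_s - float(w_s @ (mu / sd))
            active = [
                data.variable_names[j]
                for j in range(k)
                if abs(w_s[j]) > 1e-8 * max(1.0, np.abs(w_s).max())
            ]
            witness = {"direction": w, "intercept": c, "variables": active}
    return SeparationReport(separated=separated, quasi_separated=quasi, witness=witness)
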