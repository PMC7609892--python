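"""Two-stage logistic-regression fusion of per-variable log-LR scores.

Stage 1 fits, on a *training* set only, a pair of class-conditional
densities per variable and turns each measurement into a score
``s_j = log f(x_j|H1)/f(x_j|H2)``.  Stage 2 fits, on a *validation* set
only, a (penalized) logistic regression over the score vector,

    logit(p) = b*0 + b*1 s1 + ... + b*k sk,

whose fitted log-odds is the calibrated fused log-LR (prior odds 1).  The
two stages must never share rows — sharing them produces overly optimistic
calibration, which is why the split is enforced here rather than advised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import expit

from .datasets import LabeledDataset
from .density import DensityModel, fit_density, score_log_lr
from .exceptions import (
    DataLeakageError,
    DegenerateDataError,
    InvalidConfigError,
    ShapeError,
)
from .logistic import FittedGLM, fit_logistic_mle
from .metrics import LR_SATURATION, LRResult, verbal_scale
from .penalized import (
    PenaltyConfig,
    fit_bayes_glm,
    fit_elastic_net,
    fit_firth,
    select_lambda_cv,
)

__all__ = [
    "FusionModel",
    "fit_fusion",
    "predict_fusion",
    "fit_glm_by_method",
    "score_matrix",
    "lr_results_from_log_lr",
]

logger = logging.getLogger(__name__)


@dataclass
class FusionModel:
    density_models: tuple[tuple[DensityModel, DensityModel], ...]  # (pos, neg)
    fusion_fit: FittedGLM
    variables: tuple[str, ...]
    density_method: str
    fusion_method: str
    positive_label: str = "positive"
    negative_label: str = "negative"
    # per-variable (low, high) clip range for scores, from the training
    # rows: outside the training support a density ratio is extrapolation
    # noise, so scores are capped at the most extreme value the densities
    # were actually fitted to produce
    score_bounds: Optional[np.ndarray] = None


def fit_glm_by_method(
    data: LabeledDataset,
    method: str,
    penalty: Optional[PenaltyConfig] = None,
    seed: int = 0,
) -> FittedGLM:
    """Dispatch to the requested (penalized) logistic fitter."""
    penalty = penalty or PenaltyConfig(kind=method if method != "mle" else "firth")
    if method == "mle":
        return fit_logistic_mle(data)
    if method == "firth":
        return fit_firth(data)
    if method == "bayes":
        return fit_bayes_glm(
            data,
            prior_scale=penalty.prior_scale,
            prior_df=penalty.prior_df,
            intercept_prior_scale=penalty.intercept_prior_scale,
        )
    if method == "elastic_net":
        lam = penalty.lam
        if isinstance(lam, str):  # "cv"
            lam, _ = select_lambda_cv(
                data, alpha=penalty.alpha, k_folds=penalty.cv_folds, seed=seed
            )
        return fit_elastic_net(data, alpha=penalty.alpha, lam=lam)
    raise InvalidConfigError(f"unknown fusion method {method!r}")


def score_matrix(
    X: np.ndarray, density_models: Sequence[tuple[DensityModel, DensityModel]]
) -> np.ndarray:
    """Per-variable log-LR scores for each row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != len(density_models):
        raise ShapeError(
            f"expected {len(density_models)} columns, got {X.shape[1]}"
        )
    cols = [
        score_log_lr(X[:, j], pos, neg)
        for j, (pos, neg) in enumerate(density_models)
    ]
    return np.column_stack(cols)


def _check_disjoint(train: LabeledDataset, validation: LabeledDataset) -> None:
    seen = {row.tobytes() for row in np.ascontiguousarray(train.features)}
    overlap = sum(
        row.tobytes() in seen for row in np.ascontiguousarray(validation.features)
    )
    if overlap:
        raise DataLeakageError(
            f"{overlap} identical rows shared between train and validation"
        )


def fit_fusion(
    train: LabeledDataset,
    validation: LabeledDataset,
    density_method: str = "kde",
    fusion_method: str = "elastic_net",
    penalty: Optional[PenaltyConfig] = None,
    seed: int = 0,
    clip_scores: bool = True,
) -> FusionModel:
    """Fit the two-stage fusion model with strict data segregation.

    Densities see only ``train``; the fusion GLM sees only ``validation``
    scores.  Variables whose density fit degenerates (constant within a
    class in the training set) are dropped with a warning.

    With ``clip_scores`` (default), each variable's scores are clipped to
    the range the training rows themselves produce.  Beyond the training
    support the density ratio is dominated by bandwidth asymmetry and the
    evaluation floor — numerically finite but evidentially meaningless —
    and a single such score can swing a fused LR by hundreds of orders of
    magnitude.  Capping at the observed envelope keeps extrapolated items
    at "as strong as anything seen in training", never stronger.
    """
    train.require_both_classes()
    validation.require_both_classes()
    if train.variable_names != validation.variable_names:
        raise InvalidConfigError("train and validation must share variables")
    _check_disjoint(train, validation)

    pos = train.features[train.labels == 1]
    neg = train.features[train.labels == 0]
    models: list[tuple[DensityModel, DensityModel]] = []
    kept: list[str] = []
    kept_idx: list[int] = []
    for j, name in enumerate(train.variable_names):
        try:
            mp = fit_density(pos[:, j], density_method)
            mn = fit_density(neg[:, j], density_method)
        except DegenerateDataError:
            logger.warning("dropping variable %r: degenerate density fit", name)
            continue
        models.append((mp, mn))
        kept.append(name)
        kept_idx.append(j)
    if not models:
        raise DegenerateDataError("every variable had a degenerate density fit")

    bounds = None
    if clip_scores:
        S_train = score_matrix(train.features[:, kept_idx], models)
        bounds = np.vstack([S_train.min(axis=0), S_train.max(axis=0)])

    S = score_matrix(validation.features[:, kept_idx], models)
    if bounds is not None:
        S = np.clip(S, bounds[0], bounds[1])
    score_data = LabeledDataset(
        features=S,
        labels=validation.labels,
        variable_names=tuple(f"s_{name}" for name in kept),
        positive_label=validation.positive_label,
        negative_label=validation.negative_label,
    )
    fusion_fit = fit_glm_by_method(score_data, fusion_method, penalty, seed=seed)
    return FusionModel(
        density_models=tuple(models),
        fusion_fit=fusion_fit,
        variables=tuple(kept),
        density_method=density_method,
        fusion_method=fusion_method,
        positive_label=train.positive_label,
        negative_label=train.negative_label,
        score_bounds=bounds,
    )


def fused_log_lr(model: FusionModel, X: np.ndarray) -> np.ndarray:
    """Natural-log fused LR (the fitted log-odds at prior odds 1)."""
    S = score_matrix(X, model.density_models)
    if model.score_bounds is not None:
        S = np.clip(S, model.score_bounds[0], model.score_bounds[1])
    coef = model.fusion_fit.coefficients
    return coef[0] + S @ coef[1:]


def lr_results_from_log_lr(
    log_lr: np.ndarray,
    prior_odds: float = 1.0,
    threshold: float = 0.5,
    positive_label: str = "positive",
    negative_label: str = "negative",
) -> list[LRResult]:
    """Package natural-log LRs into LRResult records.

    LR is reported at prior odds 1 (the evidential quantity); the posterior
    probability folds in the user's prior odds; the class calls positive
    when that posterior reaches ``threshold`` (ties to positive).
    """
    if prior_odds <= 0:
        raise InvalidConfigError("prior_odds must be positive")
    log_lr = np.atleast_1d(np.asarray(log_lr, dtype=float))
    out = []
    log_cap = np.log(LR_SATURATION)
    for v in log_lr:
        saturated = abs(v) > log_cap
        lr = float(np.exp(np.clip(v, -log_cap, log_cap)))
        p = float(expit(v + np.log(prior_odds)))
        cls = positive_label if p >= threshold else negative_label
        out.append(
            LRResult(
                lr=lr,
                log10_lr=float(v / np.log(10.0)),
                posterior_p=p,
                predicted_class=cls,
                verbal=verbal_scale(lr),
                saturated=saturated,
            )
        )
    return out


def predict_fusion(
    model: FusionModel,
    newdata: np.ndarray,
    prior_odds: float = 1.0,
    threshold: float = 0.5,
) -> list[LRResult]:
    """Score new rows and return their fused LR results."""
    return lr_results_from_log_lr(
        fused_log_lr(model, newdata),
        prior_odds=prior_odds,
        threshold=threshold,
        positive_label=model.positive_label,
        negative_label=model.negative_label,
    )
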