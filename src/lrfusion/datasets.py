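"""Synthetic two-class datasets with the structure of biomarker panels.

The generator emulates the statistical shape of chronic-alcohol biomarker
data: a modest number of positively skewed, mutually correlated continuous
markers measured on two groups, where a subset of markers (think EtG and
FAEEs in hair) may *perfectly separate* the groups.  Perfect separation is
the failure mode that motivates penalized logistic regression, so the
generator can switch it on and off exactly.

Marginals are lognormal with a class-specific location shift; dependence is
imposed through a Gaussian copula (correlated standard normals pushed
through ``exp``).  All randomness uses :class:`numpy.random.Generator` with
the PCG64 bit generator, so a seed pins the dataset bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .exceptions import DegenerateLabelsError, InvalidConfigError, ShapeError

__all__ = [
    "LabeledDataset",
    "GeneratorConfig",
    "generate_biomarker_like",
    "generate_logistic",
    "example_dataset",
]

# log-scale class-location shift: strong for the separating markers (direct
# biomarkers), moderate for the rest (indirect biomarkers)
_SHIFT_SEPARATING = 1.0
_SHIFT_OTHER = 0.5


@dataclass(frozen=True)
class LabeledDataset:
    """An n x k feature matrix with binary class labels.

    ``labels`` is an integer vector with 1 for the positive class and 0 for
    the negative class; the string names used on disk are carried alongside.
    """

    features: np.ndarray
    labels: np.ndarray
    variable_names: tuple[str, ...]
    positive_label: str = "positive"
    negative_label: str = "negative"

    def __post_init__(self) -> None:
        X = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels)
        if X.ndim != 2:
            raise ShapeError("features must be a 2-D matrix")
        if X.shape[0] < 1:
            raise InvalidConfigError("dataset must contain at least one row")
        if y.shape != (X.shape[0],):
            raise ShapeError("labels must be a vector with one entry per row")
        if not np.isin(y, (0, 1)).all():
            raise InvalidConfigError("labels must be coded 0/1")
        names = tuple(self.variable_names)
        if len(names) != X.shape[1]:
            raise ShapeError("variable_names must match the number of columns")
        if len(set(names)) != len(names):
            raise InvalidConfigError("variable_names must be unique")
        object.__setattr__(self, "features", X)
        object.__setattr__(self, "labels", y.astype(np.int8))
        object.__setattr__(self, "variable_names", names)

    @property
    def n(self) -> int:
        return self.features.shape[0]

    @property
    def k(self) -> int:
        return self.features.shape[1]

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def n_negative(self) -> int:
        return int(self.n - self.labels.sum())

    def has_both_classes(self) -> bool:
        return 0 < self.n_positive < self.n

    def require_both_classes(self) -> None:
        if not self.has_both_classes():
            raise DegenerateLabelsError(
                "fitting requires both classes to be present"
            )

    def subset(self, idx: np.ndarray) -> "LabeledDataset":
        """Row subset keeping names and label coding."""
        idx = np.asarray(idx)
        return replace(self, features=self.features[idx], labels=self.labels[idx])

    def label_strings(self) -> np.ndarray:
        return np.where(
            self.labels == 1, self.positive_label, self.negative_label
        )


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the biomarker-like generator.

    separation_vars/separation_gap reproduce, on demand, the pattern where a
    subset of markers perfectly separates the classes: after sampling, the
    positive class is shifted up in those columns until
    ``min(positives) - max(negatives) >= separation_gap``.  With gap 0 no
    shift is applied and the classes overlap in every marker.
    """

    n: int = 125
    k: int = 8
    class_balance: float = 0.5
    separation_vars: tuple[int, ...] = (0, 1)
    separation_gap: float = 0.5
    correlation: float | np.ndarray = 0.3
    skew: float | np.ndarray = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1 or self.k < 1:
            raise InvalidConfigError("n and k must be positive")
        if not 0.0 < self.class_balance < 1.0:
            raise InvalidConfigError("class_balance must lie in (0, 1)")
        if self.separation_gap < 0:
            raise InvalidConfigError("separation_gap must be nonnegative")
        sep = tuple(int(v) for v in self.separation_vars)
        if any(v < 0 or v >= self.k for v in sep):
            raise InvalidConfigError("separation_vars must index 0..k-1")
        object.__setattr__(self, "separation_vars", sep)
        # materialize and validate the correlation matrix once
        object.__setattr__(self, "_corr", _correlation_matrix(self.correlation, self.k))
        skew = np.broadcast_to(np.asarray(self.skew, dtype=float), (self.k,)).copy()
        if (skew < 0).any():
            raise InvalidConfigError("skew must be nonnegative")
        object.__setattr__(self, "_skew", skew)

    _corr: np.ndarray = field(init=False, repr=False, compare=False, default=None)
    _skew: np.ndarray = field(init=False, repr=False, compare=False, default=None)


def _correlation_matrix(correlation: float | np.ndarray, k: int) -> np.ndarray:
    if np.isscalar(correlation):
        rho = float(correlation)
        R = np.full((k, k), rho)
        np.fill_diagonal(R, 1.0)
    else:
        R = np.asarray(correlation, dtype=float)
        if R.shape != (k, k):
            raise InvalidConfigError("correlation matrix must be k x k")
        if not np.allclose(R, R.T):
            raise InvalidConfigError("correlation matrix must be symmetric")
    try:
        np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise InvalidConfigError(
            "correlation matrix must be positive definite"
        ) from exc
    return R


def generate_biomarker_like(config: GeneratorConfig) -> LabeledDataset:
    """Draw a two-class lognormal biomarker panel per ``config``.

    Labels are Bernoulli(class_balance) per row, so realized class
    proportions fluctuate binomially around the target.  Separation, when
    requested, is enforced post hoc by an additive shift of the positive
    class in each separating column, which guarantees the gap exactly.
    """
    rng = np.random.default_rng(config.seed)
    n, k = config.n, config.k
    y = (rng.random(n) < config.class_balance).astype(np.int8)

    L = np.linalg.cholesky(config._corr)
    Z = rng.standard_normal((n, k)) @ L.T

    shift = np.full(k, _SHIFT_OTHER)
    shift[list(config.separation_vars)] = _SHIFT_SEPARATING
    log_x = config._skew * Z + shift * y[:, None]
    X = np.exp(log_x)

    if config.separation_gap > 0 and 0 < y.sum() < n:
        pos = y == 1
        for v in config.separation_vars:
            delta = X[~pos, v].max() + config.separation_gap - X[pos, v].min()
            if delta > 0:
                X[pos, v] += delta

    names = tuple(f"marker{j + 1}" for j in range(k))
    return LabeledDataset(features=X, labels=y, variable_names=names)


def generate_logistic(n: int, beta: np.ndarray, seed: int = 0) -> LabeledDataset:
    """Standard-normal features with labels from a logistic model.

    ``beta`` is (intercept, slope_1, ..., slope_k); features are i.i.d.
    N(0, 1), and each label is Bernoulli with p = expit(b0 + x @ b).
    """
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    if beta.size == 0:
        raise InvalidConfigError("beta must contain at least an intercept")
    if n < 1:
        raise InvalidConfigError("n must be positive")
    k = beta.size - 1
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, k))
    eta = beta[0] + (X @ beta[1:] if k else 0.0)
    p = 1.0 / (1.0 + np.exp(-eta))
    y = (rng.random(n) < p).astype(np.int8)
    names = tuple(f"x{j + 1}" for j in range(k))
    return LabeledDataset(features=X, labels=y, variable_names=names)


_EXAMPLE_SEEDS = {"separated": 20_101, "overlapping": 20_102, "null": 20_103}


def example_dataset(name: str) -> LabeledDataset:
    """Three fixed example panels: 'separated', 'overlapping', 'null'.

    Regenerated on demand from frozen seeds, so they are bit-stable across
    sessions without shipping data files.
    """
    if name not in _EXAMPLE_SEEDS:
        raise InvalidConfigError(
            f"unknown example {name!r}; choose from {sorted(_EXAMPLE_SEEDS)}"
        )
    seed = _EXAMPLE_SEEDS[name]
    if name == "separated":
        cfg = GeneratorConfig(seed=seed)
    elif name == "overlapping":
        cfg = GeneratorConfig(separation_gap=0.0, seed=seed)
    else:  # null: no class signal at all
        cfg = GeneratorConfig(separation_vars=(), separation_gap=0.0, seed=seed)
        ds = generate_biomarker_like(cfg)
        rng = np.random.default_rng(seed + 1)
        # resample features independently of labels to kill the class shift
        X = np.exp(0.6 * rng.standard_normal(ds.features.shape))
        return replace(ds, features=X)
    return generate_biomarker_like(cfg)
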