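"""Repeated-split comparison study across LR and classification methods.

Each replicate draws a stratified random 50/40/10 train/validation/test
split.  Fusion methods follow the two-stage protocol (densities on train,
fusion GLM on validation); plain classification methods pool train and
validation for fitting, so all non-test data is used.  Every method is
evaluated on the test rows only, by the confusion-matrix measures and the
Cllr of its test LRs.  Replicates where a fitter fails or does not converge
are excluded from that method's averages, with the exclusion counted and
reported — they are never silently averaged in.

One master seed spawns one child seed per replicate, so all methods see
identical partitions and the whole report is bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datasets import LabeledDataset
from .exceptions import InvalidConfigError, StratificationError
from .fusion import (
    fit_fusion,
    fit_glm_by_method,
    lr_results_from_log_lr,
    predict_fusion,
)
from .discriminant import fit_discriminant, predict_discriminant
from .metrics import (
    METRIC_NAMES,
    MetricsReport,
    classification_metrics,
    cllr,
    confusion_matrix,
    saturate_lrs,
)
from .penalized import PenaltyConfig

__all__ = [
    "MethodSpec",
    "HarnessConfig",
    "ReplicateRecord",
    "EvaluationReport",
    "default_method_grid",
    "run_comparison",
    "summarize_report",
]

logger = logging.getLogger(__name__)

_GLM_FITTERS = {"mle", "firth", "bayes", "elastic_net"}
_DISCRIMINANTS = {"lda", "qda"}


@dataclass(frozen=True)
class MethodSpec:
    """One column of the comparison: how to fit and how to get LRs."""

    kind: str  # "fusion" | "classification"
    fitter: str  # mle/firth/bayes/elastic_net or lda/qda
    density: Optional[str] = None  # gaussian/kde, fusion only

    def __post_init__(self) -> None:
        if self.kind not in {"fusion", "classification"}:
            raise InvalidConfigError(f"unknown method kind {self.kind!r}")
        if self.kind == "fusion":
            if self.fitter not in _GLM_FITTERS:
                raise InvalidConfigError(f"unknown fusion fitter {self.fitter!r}")
            if self.density not in {"gaussian", "kde"}:
                raise InvalidConfigError("fusion needs density gaussian|kde")
        elif self.fitter not in _GLM_FITTERS | _DISCRIMINANTS:
            raise InvalidConfigError(f"unknown classifier {self.fitter!r}")

    @property
    def name(self) -> str:
        short = {"elastic_net": "glmnet"}.get(self.fitter, self.fitter)
        if self.kind == "fusion":
            return f"fusion-{short}-{self.density}"
        return f"classification-{short}"


def default_method_grid() -> tuple[MethodSpec, ...]:
    """The study grid: 3 penalized fusion fitters x 2 densities, plus
    LDA, QDA, Firth and plain-MLE classification baselines."""
    fusions = [
        MethodSpec("fusion", fitter, density)
        for density in ("gaussian", "kde")
        for fitter in ("firth", "elastic_net", "bayes")
    ]
    classifiers = [
        MethodSpec("classification", f) for f in ("lda", "qda", "firth", "mle")
    ]
    return tuple(fusions + classifiers)


@dataclass(frozen=True)
class HarnessConfig:
    methods: tuple[MethodSpec, ...] = field(default_factory=default_method_grid)
    n_cv: int = 50
    split: tuple[float, float, float] = (0.5, 0.4, 0.1)
    threshold: float = 0.5
    seed: int = 0
    stratified: bool = True
    penalty: PenaltyConfig = field(
        default_factory=lambda: PenaltyConfig(kind="elastic_net")
    )

    def __post_init__(self) -> None:
        if self.n_cv < 1:
            raise InvalidConfigError("n_cv must be at least 1")
        s = tuple(float(v) for v in self.split)
        if len(s) != 3 or any(v <= 0 for v in s) or abs(sum(s) - 1.0) > 1e-9:
            raise InvalidConfigError(
                "split must be three positive proportions summing to 1"
            )
        object.__setattr__(self, "split", s)
        object.__setattr__(self, "methods", tuple(self.methods))


@dataclass
class ReplicateRecord:
    method: str
    replicate: int
    status: str  # "ok" | "failed" | "not_converged"
    metrics: Optional[MetricsReport] = None
    separation_flag: bool = False
    message: str = ""


@dataclass
class EvaluationReport:
    config: HarnessConfig
    records: list[ReplicateRecord]
    splits: list[tuple[np.ndarray, np.ndarray, np.ndarray]]
    replicate_seeds: list[int]

    def method_records(self, method: str) -> list[ReplicateRecord]:
        return [r for r in self.records if r.method == method]

    def failure_count(self, method: str) -> int:
        return sum(r.status != "ok" for r in self.method_records(method))

    def separation_count(self, method: str) -> int:
        return sum(r.separation_flag for r in self.method_records(method))

    def method_means(self, method: str) -> dict[str, Optional[float]]:
        """Per-metric mean over OK replicates, skipping undefined values."""
        out: dict[str, Optional[float]] = {}
        ok = [r.metrics for r in self.method_records(method) if r.status == "ok"]
        for name in METRIC_NAMES + ("cllr",):
            vals = [
                getattr(m, name) for m in ok if getattr(m, name) is not None
            ]
            out[name] = float(np.mean(vals)) if vals else None
        return out

    @property
    def method_names(self) -> list[str]:
        seen: list[str] = []
        for r in self.records:
            if r.method not in seen:
                seen.append(r.method)
        return seen


def _largest_remainder(n: int, proportions: Sequence[float]) -> list[int]:
    exact = np.asarray(proportions, dtype=float) * n
    base = np.floor(exact).astype(int)
    rem = exact - base
    # stable tie-break: earlier partitions (train, validation, test) first
    for i in np.argsort(-rem, kind="stable")[: n - base.sum()]:
        base[i] += 1
    return base.tolist()


def stratified_split(
    labels: np.ndarray,
    proportions: tuple[float, float, float],
    rng: np.random.Generator,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random three-way split; class-wise largest-remainder allocation when
    stratified.  Raises StratificationError if any partition misses a class."""
    labels = np.asarray(labels)
    parts: list[list[int]] = [[], [], []]
    if stratified:
        for cls in (0, 1):
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            counts = _largest_remainder(idx.size, proportions)
            if min(counts) < 1:
                raise StratificationError(
                    f"class {cls} has too few rows ({idx.size}) for the split"
                )
            start = 0
            for p, c in enumerate(counts):
                parts[p].extend(idx[start : start + c].tolist())
                start += c
    else:
        idx = rng.permutation(labels.size)
        counts = _largest_remainder(labels.size, proportions)
        start = 0
        for p, c in enumerate(counts):
            parts[p].extend(idx[start : start + c].tolist())
            start += c
        for p, name in enumerate(("train", "validation", "test")):
            got = labels[np.array(parts[p], dtype=int)]
            for cls in (0, 1):
                if not (got == cls).any():
                    raise StratificationError(
                        f"class {cls} missing from the {name} partition"
                    )
    return tuple(np.array(sorted(p), dtype=int) for p in parts)


def _evaluate_method(
    spec: MethodSpec,
    data: LabeledDataset,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    test_idx: np.ndarray,
    config: HarnessConfig,
    seed: int,
) -> tuple[MetricsReport, bool, bool]:
    """Fit one method on one split; return (metrics, converged, separated)."""
    test = data.subset(test_idx)
    separated = False
    converged = True
    if spec.kind == "fusion":
        model = fit_fusion(
            data.subset(train_idx),
            data.subset(val_idx),
            density_method=spec.density,
            fusion_method=spec.fitter,
            penalty=config.penalty,
            seed=seed,
        )
        converged = model.fusion_fit.converged
        separated = model.fusion_fit.separation_flag
        results = predict_fusion(model, test.features, threshold=config.threshold)
    else:
        pooled = data.subset(np.concatenate([train_idx, val_idx]))
        if spec.fitter in _DISCRIMINANTS:
            model = fit_discriminant(pooled, kind=spec.fitter)
            results = predict_discriminant(
                model, test.features, threshold=config.threshold
            )
        else:
            fit = fit_glm_by_method(pooled, spec.fitter, config.penalty, seed=seed)
            converged = fit.converged
            separated = fit.separation_flag
            # the fitted log-odds is the log-LR at prior odds 1
            eta = fit.coefficients[0] + test.features @ fit.coefficients[1:]
            results = lr_results_from_log_lr(
                eta,
                threshold=config.threshold,
                positive_label=data.positive_label,
                negative_label=data.negative_label,
            )

    truth = test.label_strings()
    predicted = np.array([r.predicted_class for r in results])
    cm = confusion_matrix(truth, predicted, positive=data.positive_label)
    metrics = classification_metrics(cm)
    lrs, _ = saturate_lrs([r.lr for r in results])
    pos = test.labels == 1
    c = cllr(lrs[pos], lrs[~pos]) if pos.any() and (~pos).any() else None
    metrics = MetricsReport(**{**metrics.as_dict(), "cllr": c})
    return metrics, converged, separated


def run_comparison(data: LabeledDataset, config: HarnessConfig) -> EvaluationReport:
    """Run the full repeated-split comparison (see module docstring)."""
    data.require_both_classes()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_cv)
    records: list[ReplicateRecord] = []
    splits = []
    rep_seeds = []
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        rep_seeds.append(rep_seed)
        train_idx, val_idx, test_idx = stratified_split(
            data.labels, config.split, rng, stratified=config.stratified
        )
        splits.append((train_idx, val_idx, test_idx))
        for spec in config.methods:
            try:
                metrics, converged, separated = _evaluate_method(
                    spec, data, train_idx, val_idx, test_idx, config, rep_seed
                )
                status = "ok" if converged else "not_converged"
                records.append(
                    ReplicateRecord(
                        method=spec.name,
                        replicate=rep,
                        status=status,
                        metrics=metrics,
                        separation_flag=separated,
                    )
                )
            except Exception as exc:  # failure of one method, one replicate
                logger.warning(
                    "replicate %d: method %s failed: %s", rep, spec.name, exc
                )
                records.append(
                    ReplicateRecord(
                        method=spec.name,
                        replicate=rep,
                        status="failed",
                        message=str(exc),
                    )
                )
    return EvaluationReport(
        config=config, records=records, splits=splits, replicate_seeds=rep_seeds
    )


def summarize_report(report: EvaluationReport) -> pd.DataFrame:
    """Long-format summary: one row per (metric, method) with mean and
    dispersion (SD and quartiles) over OK replicates."""
    if not report.records:
        raise InvalidConfigError("report contains no replicates")
    rows = []
    for method in report.method_names:
        ok = [
            r.metrics
            for r in report.method_records(method)
            if r.status == "ok" and r.metrics is not None
        ]
        for name in METRIC_NAMES + ("cllr",):
            vals = np.array(
                [getattr(m, name) for m in ok if getattr(m, name) is not None]
            )
            if vals.size:
                q25, q50, q75 = np.percentile(vals, [25, 50, 75])
                sd = float(np.std(vals, ddof=1)) if vals.size > 1 else np.nan
                rows.append(
                    dict(
                        method=method,
                        metric=name,
                        mean=float(vals.mean()),
                        sd=sd,
                        q25=q25,
                        q50=q50,
                        q75=q75,
                        n_defined=int(vals.size),
                        n_excluded=report.failure_count(method),
                    )
                )
            else:
                rows.append(
                    dict(
                        method=method,
                        metric=name,
                        mean=np.nan,
                        sd=np.nan,
                        q25=np.nan,
                        q50=np.nan,
                        q75=np.nan,
                        n_defined=0,
                        n_excluded=report.failure_count(method),
                    )
                )
    return pd.DataFrame(rows)
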