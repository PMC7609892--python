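"""Plain logistic regression: closed forms, separation diagnostics, and the
exact linear-feasibility separation test."""

import numpy as np
import pytest

from lrfusion import (
    LabeledDataset,
    detect_separation,
    fit_logistic_mle,
    posterior_to_lr,
    predict_prob,
)
from lrfusion.exceptions import (
    CollinearityError,
    DegenerateLabelsError,
    InvalidConfigError,
    ShapeError,
)
from lrfusion.logistic import FittedGLM, log_likelihood


def intercept_only(n_pos: int, n_neg: int) -> LabeledDataset:
    n = n_pos + n_neg
    return LabeledDataset(
        np.zeros((n, 0)), np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int), ()
    )


class TestMLEClosedForms:
    @pytest.mark.parametrize(
        "n_pos,n_neg,expected",
        [(50, 50, 0.0), (30, 70, np.log(30 / 70))],
    )
    def test_intercept_only_is_logit_of_mean(self, n_pos, n_neg, expected):
        fit = fit_logistic_mle(intercept_only(n_pos, n_neg))
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(expected, abs=1e-8)

    def test_two_parameter_fit_matches_grid_maximization(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        p = 1 / (1 + np.exp(-(0.5 + x)))
        y = (rng.random(40) < p).astype(int)
        ds = LabeledDataset(x[:, None], y, ("x",))
        fit = fit_logistic_mle(ds)
        assert fit.converged

        # brute-force grid maximization of the log-likelihood, refined
        b0, b1 = 0.0, 0.0
        span = 4.0
        for _ in range(8):
            g0 = np.linspace(b0 - span, b0 + span, 41)
            g1 = np.linspace(b1 - span, b1 + span, 41)
            ll = np.array(
                [
                    [log_likelihood(np.array([a, b]), ds.features, y) for b in g1]
                    for a in g0
                ]
            )
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            b0, b1 = g0[i], g1[j]
            span /= 5.0
        assert fit.coefficients == pytest.approx([b0, b1], abs=1e-3)
        # predict_prob on the training rows reproduces the probabilities of
        # the final IRLS iteration
        np.testing.assert_allclose(
            predict_prob(fit, ds.features),
            fit.diagnostics["fitted_probabilities"],
            atol=1e-12,
        )

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        X = rng.normal(size=(120, 3))
        y = (rng.random(120) < 1 / (1 + np.exp(-(X @ [0.5, -1.0, 0.2])))).astype(int)
        ds = LabeledDataset(X, y, ("a", "b", "c"))
        fit = fit_logistic_mle(ds)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.std_errors, ref.bse, rtol=1e-4)

    def test_loglik_nondecreasing_over_iterations(self, sep1d):
        fit = fit_logistic_mle(sep1d)
        path = fit.diagnostics["loglik_path"]
        assert (np.diff(path) >= -1e-8 * (1.0 + np.abs(path[:-1]))).all()


class TestSeparationSymptoms:
    def test_separated_toy_flagged_with_huge_se_ratio(self, sep1d):
        fit = fit_logistic_mle(sep1d)
        assert fit.separation_flag
        assert not fit.converged
        # the Std-error-orders-of-magnitude symptom on the slope
        assert fit.se_coef_ratios()[1] > 1e2

    def test_single_class_rejected(self):
        ds = LabeledDataset(np.arange(4.0)[:, None], np.ones(4, dtype=int), ("x",))
        with pytest.raises(DegenerateLabelsError):
            fit_logistic_mle(ds)

    def test_constant_column_rejected(self):
        ds = LabeledDataset(
            np.column_stack([np.arange(6.0), np.ones(6)]),
            np.array([0, 0, 0, 1, 1, 1]),
            ("x", "const"),
        )
        with pytest.raises(CollinearityError):
            fit_logistic_mle(ds)


class TestPredictProb:
    def test_zero_coefficients_give_half(self):
        fit = FittedGLM(method="mle", coefficients=np.zeros(3))
        assert predict_prob(fit, np.random.default_rng(0).normal(size=(5, 2))) == (
            pytest.approx([0.5] * 5)
        )

    def test_intercept_ln3_gives_three_quarters(self):
        fit = FittedGLM(method="mle", coefficients=np.array([np.log(3.0)]))
        assert predict_prob(fit, np.zeros((1, 0)))[0] == pytest.approx(0.75)

    def test_monotone_in_positive_coefficient(self):
        fit = FittedGLM(method="mle", coefficients=np.array([0.3, 1.7]))
        x = np.linspace(-5, 5, 101)[:, None]
        p = predict_prob(fit, x)
        assert (np.diff(p) > 0).all()
        assert ((p > 0) & (p < 1)).all()

    def test_dimension_mismatch(self):
        fit = FittedGLM(method="mle", coefficients=np.zeros(3))
        with pytest.raises(ShapeError):
            predict_prob(fit, np.zeros((4, 3)))


class TestPosteriorToLR:
    @pytest.mark.parametrize(
        "p,prior_odds,expected",
        [(0.5, 1.0, 1.0), (0.9, 1.0, 9.0), (0.9, 3.0, 3.0)],
    )
    def test_values(self, p, prior_odds, expected):
        lr, saturated = posterior_to_lr(p, prior_odds)
        assert lr == pytest.approx(expected)
        assert not saturated

    def test_saturation(self):
        assert posterior_to_lr(1.0) == (np.inf, True)
        assert posterior_to_lr(0.0) == (0.0, True)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidConfigError):
            posterior_to_lr(1.2)
        with pytest.raises(InvalidConfigError):
            posterior_to_lr(0.5, prior_odds=0.0)


class TestDetectSeparation:
    def test_one_dimensional_threshold(self, sep1d):
        rep = detect_separation(sep1d)
        assert rep.separated
        assert rep.witness["variables"] == ["x"]
        # the witness direction classifies the training data perfectly
        w, c = rep.witness["direction"], rep.witness["intercept"]
        margins = sep1d.features @ w + c
        z = np.where(sep1d.labels == 1, 1.0, -1.0)
        assert (z * margins > 0).all()

    def test_overlap_not_separated(self, overlap1d):
        rep = detect_separation(overlap1d)
        assert not rep.separated and not rep.quasi_separated

    def test_quasi_separation_with_boundary_point(self):
        ds = LabeledDataset(
            np.array([[1.0], [2.0], [3.0], [3.0], [4.0], [5.0]]),
            np.array([0, 0, 0, 1, 1, 1]),
            ("x",),
        )
        rep = detect_separation(ds)
        assert rep.quasi_separated and not rep.separated

    def test_two_dimensional_combination_only(self):
        # neither coordinate separates alone, but x1 + x2 does
        X = np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5], [0.0, 3.0], [3.0, 0.0], [2.0, 2.0]])
        y = np.array([0, 0, 0, 1, 1, 1])
        ds = LabeledDataset(X, y, ("x1", "x2"))
        for v in range(2):
            lo = max(X[y == 1, v].min(), X[y == 0, v].min())
            hi = min(X[y == 1, v].max(), X[y == 0, v].max())
            assert lo <= hi  # marginal overlap
        rep = detect_separation(ds)
        assert rep.separated

        # brute-force oracle: scan directions on a fine angular grid
        z = np.where(y == 1, 1.0, -1.0)
        found = False
        for theta in np.linspace(0, np.pi, 3601):
            w = np.array([np.cos(theta), np.sin(theta)])
            proj = X @ w
            for sgn in (1.0, -1.0):
                m = sgn * proj * z
                # a threshold exists iff min over pos side exceeds max neg side
                if (
                    (sgn * proj)[y == 1].min() > (sgn * proj)[y == 0].max()
                ):
                    found = True
        assert found == rep.separated

    def test_synthetic_panel_detected(self, study_panel, overlapping_panel):
        assert detect_separation(study_panel).separated
        rep = detect_separation(overlapping_panel)
        assert not rep.separated
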