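"""Firth, elastic-net and Bayes-GLM fitters: closed forms, brute-force
objective oracles, KKT conditions, and separation robustness."""

import subprocess

import numpy as np
import pytest
from scipy.special import logit

from lrfusion import (
    LabeledDataset,
    bootstrap_se,
    detect_separation,
    fit_bayes_glm,
    fit_elastic_net,
    fit_firth,
    fit_logistic_mle,
    generate_logistic,
    select_lambda_cv,
)
from lrfusion.exceptions import ConvergenceError, InvalidConfigError
from lrfusion.logistic import FittedGLM
from lrfusion.penalized import (
    bayes_log_posterior,
    elastic_net_kkt_violation,
    elastic_net_objective,
    elastic_net_penalty,
    firth_penalized_loglik,
    lambda_max,
)


def intercept_only(n_pos: int, n_neg: int) -> LabeledDataset:
    n = n_pos + n_neg
    return LabeledDataset(
        np.zeros((n, 0)), np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int), ()
    )


def grid_maximize_2d(objective, b0=0.0, b1=0.0, span=8.0, rounds=9, size=41):
    """Refined brute-force maximization over (intercept, slope)."""
    for _ in range(rounds):
        g0 = np.linspace(b0 - span, b0 + span, size)
        g1 = np.linspace(b1 - span, b1 + span, size)
        vals = np.array([[objective(np.array([a, b])) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        b0, b1 = g0[i], g1[j]
        span /= 5.0
    return np.array([b0, b1])


def mirror_symmetric_1d() -> LabeledDataset:
    """Classes that are mirror images about 0 — intercept must vanish."""
    x = np.r_[-np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0, 4.0])]
    y = np.r_[np.zeros(4), np.ones(4)].astype(int)
    return LabeledDataset(x[:, None], y, ("x",))


class TestFirth:
    def test_intercept_only_closed_form(self):
        # penalized score k - np + (1 - 2p)/2 = 0  =>  p = (k + 1/2)/(n + 1)
        fit = fit_firth(intercept_only(0, 10), tol=1e-12)
        p_hat = 0.5 / 11.0
        assert fit.converged
        assert fit.coefficients[0] == pytest.approx(np.log(1.0 / 21.0), abs=1e-8)
        assert fit.coefficients[0] == pytest.approx(logit(p_hat), abs=1e-8)

    @pytest.mark.parametrize("n_pos,n_neg", [(3, 7), (5, 5)])
    def test_intercept_only_general(self, n_pos, n_neg):
        n = n_pos + n_neg
        fit = fit_firth(intercept_only(n_pos, n_neg), tol=1e-12)
        assert fit.coefficients[0] == pytest.approx(
            logit((n_pos + 0.5) / (n + 1)), abs=1e-8
        )

    def test_separated_toy_finite_and_matches_grid_oracle(self, sep1d):
        fit = fit_firth(sep1d)
        assert fit.converged
        assert np.isfinite(fit.coefficients).all()
        assert abs(fit.coefficients[1]) < 20
        oracle = grid_maximize_2d(
            lambda b: firth_penalized_loglik(
                b, sep1d.features, sep1d.labels.astype(float)
            )
        )
        assert fit.coefficients == pytest.approx(oracle, abs=1e-3)

    def test_symmetric_data_zero_intercept(self):
        fit = fit_firth(mirror_symmetric_1d())
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-6)

    def test_penalized_loglik_nondecreasing(self, sep1d, study_panel):
        for ds in (sep1d, study_panel):
            fit = fit_firth(ds)
            path = fit.diagnostics["penalized_loglik_path"]
            assert (np.diff(path) >= -1e-7 * (1.0 + np.abs(path[:-1]))).all()

    def test_finite_on_separated_panel(self, study_panel):
        fit = fit_firth(study_panel)
        assert np.isfinite(fit.coefficients).all()
        assert np.isfinite(fit.std_errors).all()


def _zero_success() -> LabeledDataset:
    return intercept_only(0, 10)


class TestElasticNet:
    def test_penalty_evaluation(self):
        beta = np.array([1.0, 1.0])
        assert elastic_net_penalty(beta, 0.0) == pytest.approx(1.0)
        assert elastic_net_penalty(beta, 1.0) == pytest.approx(2.0)
        assert elastic_net_penalty(beta, 0.5) == pytest.approx(1.5)

    def test_huge_lambda_gives_null_model(self):
        ds = generate_logistic(100, np.array([0.0, 1.5]), seed=8)
        n_pos = int(ds.labels.sum())
        fit = fit_elastic_net(ds, alpha=1.0, lam=10.0)
        assert (fit.coefficients[1:] == 0.0).all()
        assert fit.coefficients[0] == pytest.approx(
            logit(n_pos / ds.n), abs=1e-8
        )

    def test_lambda_zero_matches_mle(self):
        ds = generate_logistic(150, np.array([0.2, 1.0, -0.7]), seed=3)
        assert not detect_separation(ds).separated
        en = fit_elastic_net(ds, alpha=1.0, lam=0.0)
        mle = fit_logistic_mle(ds)
        np.testing.assert_allclose(en.coefficients, mle.coefficients, atol=1e-4)

    @pytest.mark.parametrize("alpha,lam", [(1.0, 0.05), (0.5, 0.1), (0.0, 0.2)])
    def test_matches_grid_maximization(self, alpha, lam):
        ds = generate_logistic(60, np.array([0.3, 1.2]), seed=5)
        fit = fit_elastic_net(ds, alpha=alpha, lam=lam)
        # oracle maximizes the penalized objective on the *standardized*
        # scale, where the penalty applies
        Xs = (ds.features - fit.scale_info["center"]) / fit.scale_info["scale"]
        y = ds.labels.astype(float)

        def objective(b):
            return elastic_net_objective(b, Xs, y, alpha, lam)

        oracle = grid_maximize_2d(objective, span=4.0)
        ours = fit.diagnostics["standardized_coefficients"]
        assert ours == pytest.approx(oracle, abs=1e-3)

    def test_kkt_conditions_hold(self, study_panel):
        for alpha, lam in [(1.0, 0.02), (0.5, 0.05), (0.25, 0.01)]:
            fit = fit_elastic_net(study_panel, alpha=alpha, lam=lam)
            assert elastic_net_kkt_violation(study_panel, fit, alpha, lam) < 1e-6

    def test_exact_zeros_under_lasso(self, study_panel):
        fit = fit_elastic_net(study_panel, alpha=1.0, lam=0.05)
        assert (fit.coefficients[1:] == 0.0).sum() >= 4  # variables dropped

    def test_matches_r_glmnet(self, tmp_path):
        """Independent cross-check against the R reference implementation."""
        ds = generate_logistic(100, np.array([0.3, 1.0, -0.5, 0.0]), seed=2)
        xf, yf = tmp_path / "x.csv", tmp_path / "y.csv"
        np.savetxt(xf, ds.features, delimiter=",")
        np.savetxt(yf, ds.labels, delimiter=",")
        script = f"""
        suppressMessages(library(glmnet))
        x <- as.matrix(read.csv("{xf}", header=FALSE))
        y <- scan("{yf}", quiet=TRUE)
        f <- glmnet(x, y, family="binomial", alpha=0.5,
                    lambda=c(0.4, 0.2, 0.1, 0.05), standardize=TRUE,
                    thresh=1e-14, maxit=1e6)
        cat(as.numeric(coef(f, s=0.05, exact=TRUE, x=x, y=y)), sep=",")
        """
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        fit = fit_elastic_net(ds, alpha=0.5, lam=0.05)
        np.testing.assert_allclose(fit.coefficients, ref, atol=1e-6)

    def test_invalid_arguments(self, study_panel):
        with pytest.raises(InvalidConfigError):
            fit_elastic_net(study_panel, alpha=1.5, lam=0.1)
        with pytest.raises(InvalidConfigError):
            fit_elastic_net(study_panel, alpha=0.5, lam=-0.1)


class TestLambdaCV:
    def test_top_of_path_is_null_model(self, study_panel):
        lam, path = select_lambda_cv(study_panel, seed=0, n_lambda=30)
        assert path.n_nonzero[0] == 0
        assert path.lambdas[0] >= lambda_max(study_panel, 1.0)

    def test_seed_determinism(self, study_panel):
        lam1, _ = select_lambda_cv(study_panel, seed=4, n_lambda=30)
        lam2, _ = select_lambda_cv(study_panel, seed=4, n_lambda=30)
        assert lam1 == lam2

    def test_nonzero_count_monotone_down_the_path(self, study_panel):
        # the active set can only grow as lambda decreases along the grid
        _, path = select_lambda_cv(study_panel, seed=0, n_lambda=40)
        diffs = np.diff(path.n_nonzero.astype(int))
        # allow occasional re-entries (ties logged), but no systematic breaks
        assert (diffs >= -1).all()
        assert path.n_nonzero[-1] >= path.n_nonzero[0]

    def test_lasso_screens_pure_noise(self):
        """Under the null, CV-tuned lasso keeps at most one noise slope in
        the vast majority of datasets."""
        hits = 0
        n_sets = 100
        for s in range(n_sets):
            ds = generate_logistic(60, np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.0]), seed=1000 + s)
            lam, path = select_lambda_cv(ds, alpha=1.0, seed=s, n_lambda=30)
            fit = fit_elastic_net(ds, alpha=1.0, lam=lam)
            if (fit.coefficients[1:] != 0.0).sum() <= 1:
                hits += 1
        assert hits >= 90

    def test_path_continuity_in_lambda(self, study_panel):
        _, path = select_lambda_cv(study_panel, seed=0, n_lambda=60)
        jumps = np.abs(np.diff(path.coefficients, axis=0)).max(axis=1)
        # geometric grid with warm starts: consecutive solutions stay close
        assert np.median(jumps) < 0.5
        assert jumps.max() < 5.0


class TestBayesGLM:
    def test_flat_prior_limit_matches_mle(self):
        ds = generate_logistic(200, np.array([0.5, 1.0]), seed=6)
        assert not detect_separation(ds).separated
        bayes = fit_bayes_glm(ds, prior_scale=1e6, intercept_prior_scale=1e6)
        mle = fit_logistic_mle(ds)
        np.testing.assert_allclose(bayes.coefficients, mle.coefficients, atol=1e-3)

    def test_separated_toy_finite(self, sep1d):
        fit = fit_bayes_glm(sep1d)
        assert fit.converged
        assert np.isfinite(fit.coefficients).all()

    def test_symmetric_data_zero_intercept(self):
        fit = fit_bayes_glm(mirror_symmetric_1d())
        assert fit.coefficients[0] == pytest.approx(0.0, abs=1e-6)

    def test_matches_grid_maximization_of_log_posterior(self):
        # construct a column already centered with SD exactly 0.5, so the
        # internal rescaling is the identity and the oracle target is the
        # unscaled posterior
        rng = np.random.default_rng(9)
        x = rng.normal(size=24)
        x = (x - x.mean()) / x.std() * 0.5
        y = (x + 0.1 * rng.normal(size=24) > 0).astype(int)
        ds = LabeledDataset(x[:, None], y, ("x",))
        fit = fit_bayes_glm(ds)

        def objective(b):
            return bayes_log_posterior(b, ds.features, ds.labels.astype(float))

        # wide initial span: the Cauchy prior lets near-separated slopes
        # travel far before the posterior turns over
        oracle = grid_maximize_2d(objective, span=40.0, rounds=12, size=81)
        assert fit.coefficients == pytest.approx(oracle, abs=1e-3)

    def test_finite_on_separated_panel(self, study_panel):
        fit = fit_bayes_glm(study_panel)
        assert np.isfinite(fit.coefficients).all()


class TestBootstrap:
    def test_constant_fitter_gives_zero_se(self, study_panel):
        def fitter(d):
            return FittedGLM(method="mle", coefficients=np.array([1.0, 2.0]))

        se = bootstrap_se(fitter, study_panel, B=20, seed=0)
        assert (se == 0.0).all()

    def test_seed_determinism(self, sep1d):
        a = bootstrap_se(fit_firth, sep1d, B=30, seed=5)
        b = bootstrap_se(fit_firth, sep1d, B=30, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_intercept_only_matches_analytic_se(self):
        ds = intercept_only(80, 120)  # n = 200
        se = bootstrap_se(fit_logistic_mle, ds, B=500, seed=2)
        p_hat = 0.4
        analytic = np.sqrt(1.0 / (200 * p_hat * (1 - p_hat)))
        assert abs(se[0] - analytic) / analytic < 0.25

    def test_excess_failures_raise(self, study_panel):
        calls = {"i": 0}

        def flaky(d):
            calls["i"] += 1
            raise RuntimeError("boom")

        with pytest.raises(ConvergenceError):
            bootstrap_se(flaky, study_panel, B=10, seed=0)


class TestSeparationRobustnessAcrossFitters:
    """The central claim: all three penalized fitters stay finite exactly
    where the MLE does not exist."""

    def test_all_fitters_finite_on_separated_data(self, sep1d, study_panel):
        for ds in (sep1d, study_panel):
            assert detect_separation(ds).separated
            for fit in (
                fit_firth(ds),
                fit_bayes_glm(ds),
                fit_elastic_net(ds, alpha=1.0, lam=0.05),
            ):
                assert np.isfinite(fit.coefficients).all()
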