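"""Unit and property tests for the gamma-divergence objective and MM loop."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from gammaboot import (
    DegenerateWeightsError,
    FitConfig,
    ModelParams,
    RegressionData,
    gamma_loglik,
    gamma_norm_constant,
    minimize_weighted_objective,
    mm_update,
    mm_weights,
    ridge_init,
    weighted_objective,
)


def _loop_gamma_loglik(params, data, gamma):
    """Independent re-evaluation of the pseudo-log-likelihood with explicit
    loops and quadrature for the density norm."""
    n = data.n
    norm_const = quad(
        lambda t: norm.pdf(t, 0.0, np.sqrt(params.sigma2)) ** (1.0 + gamma),
        -np.inf,
        np.inf,
    )[0] ** (1.0 / (1.0 + gamma))
    total = 0.0
    for i in range(n):
        mu = params.alpha + float(data.X[i] @ params.beta)
        f = norm.pdf(data.y[i], mu, np.sqrt(params.sigma2))
        total += (f / norm_const) ** gamma
    return (n / gamma) * np.log(total / n)


class TestGammaNormConstant:
    def test_gamma_zero_is_unit_norm(self):
        assert gamma_norm_constant(1.0, 0.0) == pytest.approx(1.0)

    @pytest.mark.parametrize("sigma2,gamma", [(1.0, 0.5), (4.0, 0.2), (0.3, 1.0)])
    def test_matches_quadrature(self, sigma2, gamma):
        integral = quad(
            lambda t: norm.pdf(t, 0.0, np.sqrt(sigma2)) ** (1.0 + gamma),
            -np.inf,
            np.inf,
        )[0]
        expected = integral ** (1.0 / (1.0 + gamma))
        assert gamma_norm_constant(sigma2, gamma) == pytest.approx(expected, abs=1e-10)

    def test_mean_invariance_and_domain(self):
        # the norm depends on the variance only; nonpositive variance rejected
        with pytest.raises(ValueError):
            gamma_norm_constant(0.0, 0.2)
        with pytest.raises(ValueError):
            gamma_norm_constant(-1.0, 0.2)


class TestGammaLoglik:
    def test_gamma_zero_is_normal_loglik(self, five_point_data):
        params = ModelParams(0.1, [0.5, -0.2], 1.3)
        mu = params.alpha + five_point_data.X @ params.beta
        expected = norm.logpdf(five_point_data.y, mu, np.sqrt(params.sigma2)).sum()
        assert gamma_loglik(params, five_point_data, 0.0) == pytest.approx(expected)

    def test_small_gamma_converges_to_loglik(self, five_point_data):
        params = ModelParams(0.1, [0.5, -0.2], 1.3)
        exact = gamma_loglik(params, five_point_data, 0.0)
        approx = gamma_loglik(params, five_point_data, 1e-6)
        assert approx == pytest.approx(exact, rel=1e-3)

    def test_matches_loop_oracle(self, five_point_data):
        params = ModelParams(-0.2, [1.0, 0.3], 0.8)
        expected = _loop_gamma_loglik(params, five_point_data, 0.2)
        assert gamma_loglik(params, five_point_data, 0.2) == pytest.approx(
            expected, rel=1e-10
        )

    def test_extreme_outlier_value_is_ignored(self, rng):
        # the density power of an extreme outlier vanishes, so R_gamma no
        # longer depends on the outlier's actual value, while an inlier's
        # value still matters
        X = rng.standard_normal((30, 1))
        beta = np.array([1.0])
        y = X[:, 0] * beta[0] + rng.standard_normal(30)
        params = ModelParams(0.0, beta, 1.0)

        def with_extra(resid):
            data = RegressionData(np.append(y, resid), np.vstack([X, [0.0]]))
            return gamma_loglik(params, data, 0.2)

        assert abs(with_extra(100.0) - with_extra(200.0)) < 1e-12
        assert abs(with_extra(0.0) - with_extra(1.0)) > 1e-3

    def test_nonpositive_sigma2_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(0.0, [0.0, 0.0], -1.0)
        with pytest.raises(ValueError):
            ModelParams(0.0, [0.0, 0.0], 0.0)


class TestWeightedObjective:
    def test_uniform_weights_gamma_zero_limit(self, five_point_data):
        # at gamma -> 0 with unit weights: penalized negative log-likelihood
        params = ModelParams(0.3, [0.4, -0.6], 0.9)
        config = FitConfig(gamma=0.0, S_beta=10.0, a=1.0)
        w = np.ones(5)
        mu = params.alpha + five_point_data.X @ params.beta
        nll = -norm.logpdf(five_point_data.y, mu, np.sqrt(params.sigma2)).sum()
        pen = (
            0.5 * params.beta @ params.beta / 10.0
            + (1.0 + 0.5) * np.log(params.sigma2)
            + 0.5 / params.sigma2
        )
        got = weighted_objective(params, five_point_data, w, config)
        assert got == pytest.approx(nll + pen, rel=1e-12)

    def test_matches_loop_evaluation(self, five_point_data, rng):
        params = ModelParams(0.3, [0.4, -0.6], 0.9)
        gamma = 0.2
        config = FitConfig(gamma=gamma, S_beta=50.0, a=2.0)
        w = 5 * rng.dirichlet(np.ones(5))
        n = 5
        total = 0.0
        for i in range(n):
            mu = params.alpha + float(five_point_data.X[i] @ params.beta)
            total += w[i] * norm.pdf(five_point_data.y[i], mu, np.sqrt(params.sigma2)) ** gamma
        expected = (
            -(n / gamma) * np.log(total / n)
            + 0.5 * params.beta @ params.beta / 50.0
            + (1.0 + 1.0 - n * gamma / (2 * (1 + gamma))) * np.log(params.sigma2)
            + 1.0 / params.sigma2
        )
        got = weighted_objective(params, five_point_data, w, config)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_weight_length_mismatch(self, five_point_data, default_config):
        params = ModelParams(0.0, [0.0, 0.0], 1.0)
        with pytest.raises(ValueError):
            weighted_objective(params, five_point_data, np.ones(4), default_config)

    def test_intercept_mode_adds_alpha_penalty(self, five_point_data):
        config = FitConfig(gamma=0.2, S_alpha=4.0)
        params = ModelParams(2.0, [0.0, 0.0], 1.0)
        w = np.ones(5)
        base = weighted_objective(params, five_point_data, w, config)
        with_int = weighted_objective(
            params, five_point_data, w, config, intercept_mode=True
        )
        assert with_int - base == pytest.approx(2.0**2 / (2 * 4.0))


class TestMMWeights:
    def test_symmetry_equal_residuals(self):
        X = np.zeros((4, 1))
        y = np.ones(4)  # all residuals equal
        data = RegressionData(y, X)
        params = ModelParams(0.0, [0.0], 1.0)
        s = mm_weights(params, data, np.ones(4), 0.2)
        np.testing.assert_allclose(s, np.ones(4))

    def test_outlier_gets_minimum_weight(self, rng):
        X = rng.standard_normal((20, 1))
        y = X[:, 0] + rng.standard_normal(20) * 0.5
        y[7] += 10.0  # 10-sigma outlier at sigma2=1 scale below
        data = RegressionData(y, X)
        params = ModelParams(0.0, [1.0], 1.0)
        s = mm_weights(params, data, np.ones(20), 0.2)
        assert np.argmin(s) == 7
        assert s[7] < 1.0

    def test_sums_to_n_random_inputs(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            X = rng.standard_normal((n, 2))
            y = rng.standard_normal(n) * 3
            w = n * rng.dirichlet(np.ones(n))
            params = ModelParams(
                float(rng.normal()), rng.normal(size=2), float(rng.uniform(0.1, 5.0))
            )
            s = mm_weights(params, RegressionData(y, X), w, 0.3)
            assert abs(s.sum() - n) < 1e-10 * n
            assert np.all(s >= 0)

    def test_decreasing_in_squared_residual(self):
        X = np.zeros((5, 1))
        y = np.array([0.0, 0.5, 1.0, 2.0, 4.0])
        data = RegressionData(y, X)
        params = ModelParams(0.0, [0.0], 1.0)
        s = mm_weights(params, data, np.ones(5), 0.2)
        assert np.all(np.diff(s) < 0)

    def test_degenerate_underflow_raises(self):
        # residuals so extreme that every log-density is -inf
        X = np.zeros((3, 1))
        y = np.full(3, 1e200)
        data = RegressionData(y, X)
        params = ModelParams(0.0, [0.0], 1e-6)
        with pytest.raises(DegenerateWeightsError):
            with np.errstate(over="ignore"):
                mm_weights(params, data, np.ones(3), 1.0)


class TestMMUpdate:
    def test_ols_limit(self, rng):
        # s = 1, vanishing prior, gamma -> 0: beta is OLS, sigma2 -> RSS/(n+2)
        n = 30
        X = rng.standard_normal((n, 2))
        y = X @ [1.0, -2.0] + rng.standard_normal(n)
        data = RegressionData(y, X)
        config = FitConfig(gamma=0.0, a=1e-12)
        P = np.eye(2) * 1e-12
        params = ModelParams(0.0, [0.0, 0.0], 1.0)
        out = mm_update(params, data, np.ones(n), config, prior_precision=P)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(out.beta, beta_ols, atol=1e-8)
        rss = float(((y - X @ beta_ols) ** 2).sum())
        assert out.sigma2 == pytest.approx(rss / (n + 2), rel=1e-8)

    def test_matches_explicit_linear_algebra(self, five_point_data, rng):
        config = FitConfig(gamma=0.2, S_beta=10.0, a=1.5)
        s = 5 * rng.dirichlet(np.ones(5))
        params = ModelParams(0.0, [0.2, -0.1], 0.7)
        out = mm_update(params, five_point_data, s, config)
        X, y = five_point_data.X, five_point_data.y
        A = np.zeros((2, 2))
        b = np.zeros(2)
        for i in range(5):
            A += s[i] * np.outer(X[i], X[i]) / params.sigma2
            b += s[i] * X[i] * y[i] / params.sigma2
        A += np.eye(2) / 10.0
        beta_expected = np.linalg.solve(A, b)
        np.testing.assert_allclose(out.beta, beta_expected, rtol=1e-12)
        r = y - X @ beta_expected
        sigma2_expected = (1.5 + float(s @ r**2)) / (2 + 1.5 + 5 / 1.2)
        assert out.sigma2 == pytest.approx(sigma2_expected, rel=1e-12)

    def test_intercept_shrunken_mean(self, rng):
        # beta = 0, s = 1: alpha update is the shrunken mean of y
        n = 25
        X = rng.standard_normal((n, 1))
        y = rng.standard_normal(n) + 3.0
        data = RegressionData(y, X)
        config = FitConfig(gamma=0.2, S_alpha=2.0, S_beta=1e8)
        params = ModelParams(0.0, [0.0], 1.5)
        out = mm_update(
            params, data, np.ones(n), config, intercept_mode=True
        )
        expected_alpha = (y.sum() / 1.5) / (n / 1.5 + 1 / 2.0)
        assert out.alpha == pytest.approx(expected_alpha, rel=1e-12)

    def test_sigma2_positive(self, five_point_data, rng):
        config = FitConfig(gamma=0.2, a=0.5)
        params = ModelParams(0.0, [0.0, 0.0], 1e-4)
        out = mm_update(params, five_point_data, np.ones(5), config)
        assert out.sigma2 > 0


class TestMinimize:
    def test_monotone_descent_random_fixtures(self, rng):
        # MM guarantee: the objective never increases, over many random
        # problems and random Dirichlet weights (the loop raises on increase)
        for _ in range(100):
            n = int(rng.integers(8, 50))
            p = int(rng.integers(1, 4))
            X = rng.standard_normal((n, p))
            y = X @ rng.normal(size=p) + rng.standard_normal(n) * rng.uniform(0.5, 2)
            if rng.random() < 0.3:  # sprinkle outliers
                y[: max(1, n // 10)] += rng.choice([-1, 1]) * 15.0
            data = RegressionData(y, X)
            w = n * rng.dirichlet(np.ones(n))
            config = FitConfig(gamma=float(rng.uniform(0.05, 0.7)))
            res = minimize_weighted_objective(data, w, config)
            start = ridge_init(data, intercept=False)
            initial = weighted_objective(start, data, w, config)
            assert res.objective <= initial + 1e-9 * (1 + abs(initial))

    def test_recovers_truth_on_clean_data(self, clean_data):
        data, truth = clean_data
        config = FitConfig(gamma=0.2, S_alpha=1e6, S_beta=1e6)
        res = minimize_weighted_objective(
            data, np.ones(data.n), config, intercept_mode=True
        )
        # within 2 standardized units of the generative values
        se = 1.0 / np.sqrt(data.n)
        assert abs(res.params.alpha - truth.alpha) < 2 * 3 * se
        assert np.all(np.abs(res.params.beta - truth.beta) < 2 * 3 * se)

    def test_gamma_to_zero_matches_ols(self, clean_data):
        data, _ = clean_data
        config = FitConfig(gamma=1e-6, S_alpha=1e8, S_beta=1e8, a=1e-8, mm_tol=1e-12)
        res = minimize_weighted_objective(
            data, np.ones(data.n), config, intercept_mode=True
        )
        Z = np.column_stack([np.ones(data.n), data.X])
        coef, *_ = np.linalg.lstsq(Z, data.y, rcond=None)
        assert res.params.alpha == pytest.approx(coef[0], rel=1e-3)
        np.testing.assert_allclose(res.params.beta, coef[1:], rtol=1e-3)

    def test_matches_grid_search_p1(self, rng):
        # brute-force grid oracle on a p=1 problem without intercept
        n = 20
        X = rng.standard_normal((n, 1))
        y = X[:, 0] * 1.5 + rng.standard_normal(n) * 0.7
        data = RegressionData(y, X)
        config = FitConfig(gamma=0.3, S_beta=100.0, a=1.0, mm_tol=1e-12)
        w = n * rng.dirichlet(np.ones(n))
        res = minimize_weighted_objective(data, w, config)
        betas = np.linspace(res.params.beta[0] - 0.5, res.params.beta[0] + 0.5, 400)
        sig2s = np.exp(
            np.linspace(
                np.log(res.params.sigma2) - 1.0, np.log(res.params.sigma2) + 1.0, 400
            )
        )
        # direct vectorized evaluation of the objective on the grid
        B, S = np.meshgrid(betas, sig2s, indexing="ij")  # (400, 400)
        r = y[None, None, :] - B[..., None] * X[:, 0][None, None, :]
        logf = -0.5 * (np.log(2 * np.pi * S[..., None])) - 0.5 * r**2 / S[..., None]
        gam = config.gamma
        first = -(n / gam) * (
            np.log((w[None, None, :] * np.exp(gam * logf)).sum(axis=-1)) - np.log(n)
        )
        pen = (
            0.5 * B**2 / 100.0
            + (1.0 + 0.5 - n * gam / (2 * (1 + gam))) * np.log(S)
            + 0.5 / S
        )
        grid_vals = first + pen
        i, j = np.unravel_index(np.argmin(grid_vals), grid_vals.shape)
        assert res.params.beta[0] == pytest.approx(betas[i], abs=2 * 0.5 / 399 + 1e-6)
        assert res.params.sigma2 == pytest.approx(sig2s[j], rel=2.0 / 399 * 2)
        assert res.objective <= grid_vals[i, j] + 1e-10

    def test_outlier_insensitivity_extreme(self):
        # appending an observation with a 1e6-sigma residual leaves the
        # minimizer essentially unchanged (asymptotic rejection property;
        # n large enough that the O(1/n^2) reweighting shift is below 1e-6)
        g = np.random.default_rng(42)
        n = 4000
        X = g.standard_normal((n, 2))
        y = 1.0 + X @ [2.0, -1.0] + g.standard_normal(n)
        config = FitConfig(gamma=0.2, mm_tol=1e-14, mm_max_iter=50000)
        base = minimize_weighted_objective(
            RegressionData(y, X), np.ones(n), config, intercept_mode=True
        )
        y_out = np.append(y, 1.0 + 1e6)
        X_out = np.vstack([X, [0.0, 0.0]])
        res = minimize_weighted_objective(
            RegressionData(y_out, X_out), np.ones(n + 1), config, intercept_mode=True
        )
        diff = np.abs(base.params.as_vector() - res.params.as_vector())
        assert np.all(diff < 1e-6)

    def test_nonconvergence_returns_flag(self, five_point_data):
        config = FitConfig(gamma=0.2, mm_tol=1e-16, mm_max_iter=2)
        res = minimize_weighted_objective(five_point_data, np.ones(5), config)
        assert not res.converged
        assert np.isfinite(res.objective)
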