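"""Unit tests for OLS, conjugate posterior, hybrid EM, and Wald summaries."""

import numpy as np
import pytest
from scipy import integrate, linalg, stats

from bfh.hybrid_core import (
    GaussianPrior,
    InsufficientDataError,
    InvalidPriorError,
    RankDeficiencyError,
    RegressionData,
    bayes_fit,
    conjugate_posterior,
    hybrid_em_fit,
    ols_fit,
    wald_inference,
)


def joint_fixed_point(X, Y, bayes_idx, prior):
    """Independent oracle: solve both stationarity equations as one linear system."""
    p = X.shape[1]
    B = list(bayes_idx)
    A = [j for j in range(p) if j not in B]
    XB, XA = X[:, B], X[:, A]
    prec = linalg.inv(prior.covariance)
    M = np.zeros((p, p))
    c = np.zeros(p)
    M[np.ix_(B, B)] = prec + XB.T @ XB
    M[np.ix_(B, A)] = XB.T @ XA
    M[np.ix_(A, B)] = XA.T @ XB
    M[np.ix_(A, A)] = XA.T @ XA
    c[B] = prec @ prior.mean + XB.T @ Y
    c[A] = XA.T @ Y
    return linalg.solve(M, c)


class TestOLS:
    def test_intercept_only_is_sample_mean_and_variance(self):
        fit = ols_fit(RegressionData(np.ones((4, 1)), [1, 2, 3, 4]))
        assert fit.estimate == pytest.approx([2.5])
        assert fit.sigma2 == pytest.approx(5 / 3)
        assert fit.dof == 3

    def test_orthonormal_design_reduces_to_projection(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((8, 3)))
        Y = rng.standard_normal(8)
        fit = ols_fit(RegressionData(Q, Y))
        assert fit.estimate == pytest.approx(Q.T @ Y)

    def test_fixed_integer_design_matches_generic_solver(self):
        X = np.array(
            [[1, 2, 0], [1, 1, 3], [1, 0, 1], [1, 4, 2], [1, 3, 5], [1, 2, 2]],
            dtype=float,
        )
        e = np.array([0.05, -0.02, 0.01, -0.04, 0.03, -0.03])
        Y = X @ np.array([1.0, -0.5, 0.25]) + e
        fit = ols_fit(RegressionData(X, Y))
        oracle, *_ = np.linalg.lstsq(X, Y, rcond=None)
        assert np.max(np.abs(fit.estimate - oracle)) < 1e-10
        assert np.allclose(fit.covariance, linalg.inv(X.T @ X) * fit.sigma2)

    def test_singular_design_names_collinear_columns(self):
        X = np.column_stack([np.ones(5), np.arange(5.0), 2 * np.arange(5.0)])
        with pytest.raises(RankDeficiencyError, match=r"collinear"):
            ols_fit(RegressionData(X, np.zeros(5)))

    def test_too_few_rows_raises(self):
        with pytest.raises(InsufficientDataError):
            ols_fit(RegressionData(np.eye(2), [1.0, 2.0]))


class TestConjugatePosterior:
    def test_scalar_case_closed_form(self):
        data = RegressionData(np.ones((2, 1)), [1.0, 3.0])
        prior = GaussianPrior([0.0], [[1.0]])
        post = conjugate_posterior(data, prior, sigma2=1.0)
        assert post.mean == pytest.approx([4 / 3])
        assert post.covariance[0, 0] == pytest.approx(1 / 3)

    def test_scalar_case_matches_quadrature(self):
        # numerical integration of likelihood x prior (sigma2 = 1 so the
        # scaled and face-value conventions coincide)
        y = np.array([1.0, 3.0])

        def unnorm(b):
            return np.exp(-0.5 * np.sum((y - b) ** 2)) * stats.norm.pdf(b, 0, 1)

        z0, _ = integrate.quad(unnorm, -10, 10)
        m, _ = integrate.quad(lambda b: b * unnorm(b), -10, 10)
        post = conjugate_posterior(
            RegressionData(np.ones((2, 1)), y), GaussianPrior([0.0], [[1.0]]), 1.0
        )
        assert post.mean[0] == pytest.approx(m / z0, abs=1e-8)

    def test_flat_prior_limit_recovers_ols(self, rng):
        X = np.column_stack([np.ones(15), rng.standard_normal((15, 2))])
        Y = rng.standard_normal(15) + 2
        data = RegressionData(X, Y)
        fit = ols_fit(data)
        prior = GaussianPrior(np.zeros(3), np.eye(3) * 1e8)
        post = conjugate_posterior(data, prior, fit.sigma2)
        assert np.max(np.abs(post.mean / fit.estimate - 1)) < 1e-4

    def test_dogmatic_prior_limit_returns_prior_mean(self, rng):
        X = np.column_stack([np.ones(10), rng.standard_normal(10)])
        data = RegressionData(X, rng.standard_normal(10))
        m = np.array([3.0, -1.0])
        post = conjugate_posterior(data, GaussianPrior(m, np.eye(2) * 1e-8), 1.0)
        assert np.max(np.abs(post.mean - m)) < 1e-4

    def test_nonpositive_prior_rejected(self):
        with pytest.raises(InvalidPriorError):
            GaussianPrior([0.0, 0.0], [[1.0, 2.0], [2.0, 1.0]])

    def test_invalid_sigma2_rejected(self):
        data = RegressionData(np.ones((3, 1)), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            conjugate_posterior(data, GaussianPrior([0.0], [[1.0]]), 0.0)


class TestBayesFit:
    def test_noninformative_prior_tracks_ols(self, rng):
        X = np.column_stack([np.ones(20), rng.standard_normal((20, 2))])
        Y = X @ np.array([1.0, 0.5, -0.3]) + rng.standard_normal(20) * 0.3
        data = RegressionData(X, Y)
        post = bayes_fit(data, GaussianPrior(np.zeros(3), np.eye(3) * 100))
        ols = ols_fit(data)
        assert np.max(np.abs(post.mean / ols.estimate - 1)) < 0.01

    def test_intercept_only_scalar_formula(self):
        data = RegressionData(np.ones((4, 1)), [1.0, 2.0, 3.0, 4.0])
        sigma2 = ols_fit(data).sigma2
        post = bayes_fit(data, GaussianPrior([0.0], [[100.0]]))
        expected = (1 / 100 + 4) ** -1 * (0.0 / 100 + 10.0)
        assert post.mean[0] == pytest.approx(expected)
        assert post.covariance[0, 0] == pytest.approx((1 / 100 + 4) ** -1 * sigma2)

    def test_posterior_variance_below_both_precision_bounds(self, rng):
        X = np.column_stack([np.ones(12), rng.standard_normal(12)])
        Y = rng.standard_normal(12)
        data = RegressionData(X, Y)
        v = 0.5
        post = bayes_fit(data, GaussianPrior(np.zeros(2), np.eye(2) * v))
        sigma2 = ols_fit(data).sigma2
        data_only = np.diag(linalg.inv(X.T @ X)) * sigma2
        prior_only = v * sigma2  # prior precision alone, on the sigma2 scale
        assert np.all(np.diag(post.covariance) < data_only + 1e-12)
        assert np.all(np.diag(post.covariance) < prior_only + 1e-12)


class TestHybridEM:
    def _data(self, rng, n=20):
        X = np.column_stack(
            [np.ones(n), np.repeat([0.0, 1.0], n // 2), rng.standard_normal(n)]
        )
        Y = X @ np.array([1.0, -0.6, 0.4]) + rng.standard_normal(n) * 0.5
        return RegressionData(X, Y)

    def test_noninformative_prior_matches_ols_point_estimate(self, rng):
        # on standardized data (unit-variance centered predictors and
        # response) the N(0, 100) prior is effectively flat
        n = 20
        X = np.column_stack(
            [np.ones(n), np.repeat([-1.0, 1.0], n // 2), rng.standard_normal(n)]
        )
        Y = X @ np.array([0.0, -0.3, 0.4]) + rng.standard_normal(n)
        Y = (Y - Y.mean()) / Y.std()
        data = RegressionData(X, Y)
        fit = hybrid_em_fit(data, [1], GaussianPrior([0.0], [[100.0]]))
        ols = ols_fit(data)
        assert abs(fit.estimate[1] - ols.estimate[1]) < 2e-3
        # the conditional SE is never larger than the marginal OLS SE
        assert fit.se[1] <= ols.se[1] + 1e-12

    def test_orthogonal_blocks_converge_immediately(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((12, 3)))
        Y = rng.standard_normal(12)
        data = RegressionData(Q, Y)
        prior = GaussianPrior([0.3], [[0.5]])
        fit = hybrid_em_fit(data, [1], prior)
        assert fit.converged and fit.n_iter <= 2
        marg = conjugate_posterior(
            RegressionData(Q[:, [1]], Y), prior, ols_fit(data).sigma2
        )
        assert fit.estimate[1] == pytest.approx(marg.mean[0], abs=1e-10)

    def test_fixed_point_satisfies_joint_stationarity(self, rng):
        data = self._data(rng)
        prior = GaussianPrior([-0.5], [[0.2]])
        fit = hybrid_em_fit(data, [1], prior, tol=1e-12)
        oracle = joint_fixed_point(data.X, data.Y, [1], prior)
        assert np.max(np.abs(fit.estimate - oracle)) < 1e-8

    def test_dogmatic_prior_pins_bayesian_coordinate(self, rng):
        data = self._data(rng)
        fit = hybrid_em_fit(data, [1], GaussianPrior([0.7], [[1e-10]]))
        assert fit.estimate[1] == pytest.approx(0.7, abs=1e-4)

    def test_degenerate_partitions_redirect(self, rng):
        data = self._data(rng)
        with pytest.raises(ValueError, match="ols_fit"):
            hybrid_em_fit(data, [], GaussianPrior([0.0], [[1.0]]))
        with pytest.raises(ValueError, match="bayes_fit"):
            hybrid_em_fit(
                data, [0, 1, 2], GaussianPrior(np.zeros(3), np.eye(3))
            )

    def test_nonconvergence_flagged_not_fatal(self, rng):
        data = self._data(rng)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            fit = hybrid_em_fit(
                data, [1], GaussianPrior([0.0], [[100.0]]), tol=1e-14, max_iter=1
            )
        assert not fit.converged
        assert fit.n_iter == 1

    def test_trajectory_starts_at_ols(self, rng):
        data = self._data(rng)
        fit = hybrid_em_fit(data, [1], GaussianPrior([0.0], [[1.0]]))
        assert np.allclose(fit.trajectory[0], ols_fit(data).estimate)
        assert len(fit.trajectory) == fit.n_iter + 1


class TestWald:
    @pytest.mark.parametrize(
        "est, se, p3",
        [(-0.275, 0.214, 0.199), (-0.299, 0.106, 0.005), (0.0, 1.0, 1.0)],
    )
    def test_two_sided_p(self, est, se, p3):
        s = wald_inference(est, se)
        assert s.p == pytest.approx(p3, abs=1e-3)
        assert s.ci_low == pytest.approx(est - 1.96 * se)
        assert s.ci_high == pytest.approx(est + 1.96 * se)
        assert s.ci_low < s.ci_high

    def test_zero_estimate_symmetric(self):
        s = wald_inference(0.0, 2.0)
        assert s.p == 1.0
        assert s.ci_low == -s.ci_high

    def test_invalid_se(self):
        with pytest.raises(ValueError):
            wald_inference(1.0, 0.0)
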