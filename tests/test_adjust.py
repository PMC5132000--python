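import numpy as np
import pytest
from scipy import stats

import exosurv as es
from exosurv import numdiff
from exosurv.adjust import InferenceError, maximize_constrained


def quadratic_loglik(A, mu):
    A = np.asarray(A, dtype=float)
    mu = np.asarray(mu, dtype=float)

    def f(theta):
        d = np.asarray(theta) - mu
        return float(-0.5 * d @ A @ d)

    return f


class TestNumdiff:
    def test_gradient_matches_analytic(self):
        f = lambda x: float(np.sin(x[0]) * np.exp(x[1]))
        x = np.array([0.7, -0.3])
        g = numdiff.gradient(f, x)
        expected = np.array([np.cos(0.7) * np.exp(-0.3),
                             np.sin(0.7) * np.exp(-0.3)])
        np.testing.assert_allclose(g, expected, rtol=1e-9)

    def test_hessian_matches_analytic(self):
        f = lambda x: float(x[0] ** 3 + 3 * x[0] * x[1] + x[1] ** 2)
        x = np.array([1.2, 0.4])
        H = numdiff.hessian(f, x)
        np.testing.assert_allclose(H, [[6 * 1.2, 3.0], [3.0, 2.0]], rtol=1e-7)

    def test_vector_valued_jacobian(self):
        f = lambda x: np.array([x[0] ** 2, x[0] * x[1]])
        J = numdiff.gradient(f, np.array([2.0, 3.0]))
        np.testing.assert_allclose(J, [[4.0, 0.0], [3.0, 2.0]], rtol=1e-8)


class TestScores:
    def test_exponential_rate_hand_formula(self):
        # clusters of size 1, one-parameter exponential rate model:
        # l_j(rho) = d_j log rho - rho t_j, so U_j = d_j / rho - t_j
        t = np.array([1.0, 2.0, 0.5, 3.0])
        d = np.array([1, 1, 0, 1])

        def cl(theta):
            rho = theta[0]
            return d * np.log(rho) - rho * t

        rho0 = 0.8
        scores = es.score_by_cluster(cl, np.array([rho0]))
        np.testing.assert_allclose(scores[:, 0], d / rho0 - t, rtol=1e-8)

    def test_scores_sum_to_zero_at_mle(self, medium_fit):
        scores = es.score_by_cluster(medium_fit.cluster_loglik_fn(),
                                     medium_fit.theta_hat)
        assert scores.shape[0] == 60
        total = scores.sum(axis=0)
        assert np.max(np.abs(total)) < 1e-2 * max(1, abs(medium_fit.loglik_I))

    def test_single_cluster_equals_full_gradient(self, small_dataset):
        from exosurv.frailty import FrailtyData, cluster_logliks
        data = FrailtyData.from_dataset(small_dataset)
        merged = FrailtyData(
            e_pulse=data.e_pulse, e_between=data.e_between, d=data.d,
            event_in_pulse=data.event_in_pulse, X=data.X, weight=data.weight,
            cluster=np.zeros_like(data.cluster), cluster_ids=np.array(["all"]))
        theta = np.array([-6.5, -8.5, 1.0, 6.0, 0.16, 0.1])
        scores = es.score_by_cluster(lambda th: cluster_logliks(th, merged),
                                     theta)
        grad = numdiff.gradient(lambda th: es.loglik_independence(th, data),
                                theta)
        assert scores.shape == (1, 6)
        np.testing.assert_allclose(scores[0], grad, rtol=1e-5)


class TestSandwich:
    def test_zero_scores_zero_variance(self):
        H = -np.eye(3)
        res = es.sandwich_variance(H, np.zeros((5, 3)))
        np.testing.assert_allclose(res.R, 0.0, atol=1e-15)

    def test_information_identity_recovers_naive(self):
        # V = -H in one dimension -> R = -H^-1 (robust equals naive)
        H = np.array([[-4.0]])
        scores = np.array([[2.0]])  # U^2 = 4 = -H
        res = es.sandwich_variance(H, scores)
        np.testing.assert_allclose(res.R, [[0.25]])
        np.testing.assert_allclose(res.robust_se, [0.5])

    def test_singular_hessian_rejected(self):
        with pytest.raises(InferenceError, match="singular"):
            es.sandwich_variance(np.zeros((2, 2)), np.ones((3, 2)))

    def test_robust_close_to_naive_under_independence(self, medium_fit,
                                                      medium_adjusted):
        sw, _ = medium_adjusted
        naive_se = np.sqrt(np.diag(np.linalg.inv(-medium_fit.hessian)))
        ratio = sw.robust_se / naive_se
        assert np.all((ratio > 0.7) & (ratio < 1.4))


class TestAdjustment:
    def test_identity_when_R_matches_naive(self):
        A = np.array([[2.0, 0.3], [0.3, 1.0]])
        mu = np.array([0.5, -0.2])
        f = quadratic_loglik(A, mu)
        adj = es.build_adjustment(-A, np.linalg.inv(A), mu, f)
        np.testing.assert_allclose(adj.C, np.eye(2), atol=1e-12)
        theta = np.array([1.0, 1.0])
        assert adj(theta) == pytest.approx(f(theta), abs=1e-12)

    def test_value_preserved_at_mle(self, medium_fit, medium_adjusted):
        _, adj = medium_adjusted
        assert adj(medium_fit.theta_hat) == pytest.approx(medium_fit.loglik_I,
                                                          abs=1e-9)

    def test_curvature_equals_minus_inverse_sandwich(self):
        A = np.array([[3.0, 0.5], [0.5, 2.0]])
        mu = np.zeros(2)
        R = np.array([[0.9, -0.1], [-0.1, 0.6]])
        adj = es.build_adjustment(-A, R, mu, quadratic_loglik(A, mu))
        H_A = numdiff.hessian(adj, mu)
        np.testing.assert_allclose(H_A, -np.linalg.inv(R), rtol=1e-6)

    def test_non_positive_definite_rejected(self):
        with pytest.raises(InferenceError, match="positive definite"):
            es.build_adjustment(np.eye(2), np.eye(2), np.zeros(2),
                                lambda th: 0.0)


class TestLrt:
    def _adj(self, R=1.0):
        A = np.array([[1.0]])
        f = quadratic_loglik(A, np.zeros(1))
        return es.build_adjustment(-A, np.array([[R]]), np.zeros(1), f)

    def test_interior_null_chi2_quantile(self):
        adj = self._adj(R=1.0)
        v = np.sqrt(stats.chi2.ppf(0.95, 1))  # Lambda_A = 3.841
        res = es.lrt_adjusted(adj, fixed={0: v})
        assert res.stat == pytest.approx(3.841, abs=1e-2)
        assert res.pvalue == pytest.approx(0.05, abs=1e-3)

    def test_boundary_null_mixture(self):
        adj = self._adj(R=1.0)
        v = np.sqrt(2.706)  # chi2_1 0.90 quantile: mixture p = 0.05
        res = es.lrt_adjusted(adj, fixed={0: v}, boundary=True)
        assert res.pvalue == pytest.approx(0.05, abs=1e-3)

    def test_zero_statistic_p_one(self):
        adj = self._adj()
        assert es.lrt_adjusted(adj, fixed={0: 0.0}).pvalue == 1.0
        assert es.lrt_adjusted(adj, fixed={0: 0.0}, boundary=True).pvalue == 1.0

    def test_tie_constraint(self):
        A = np.diag([2.0, 2.0])
        mu = np.array([1.0, -1.0])
        adj = es.build_adjustment(-A, np.linalg.inv(A), mu,
                                  quadratic_loglik(A, mu))
        res = es.lrt_adjusted(adj, ties=[(0, 1)])
        # constrained optimum at theta0=theta1=0: Lambda = 2*2*(1)^2/... =
        # A (1^2 + 1^2) = 4
        assert res.stat == pytest.approx(4.0, abs=1e-4)
        np.testing.assert_allclose(res.theta_constrained, [0.0, 0.0],
                                   atol=1e-4)

    def test_mixture_pvalue_halves_tail(self):
        s = 3.0
        assert es.mixture_pvalue(s, True) == pytest.approx(
            0.5 * stats.chi2.sf(s, 1))


class TestProfileCI:
    def test_gaussian_case_matches_wald(self):
        A = np.array([[4.0, 1.0], [1.0, 2.0]])
        mu = np.array([0.3, -0.7])
        R = np.linalg.inv(A)
        adj = es.build_adjustment(-A, R, mu, quadratic_loglik(A, mu))
        for k in range(2):
            lo, hi = es.profile_ci(adj, k, 0.95)
            se = np.sqrt(R[k, k])
            assert lo == pytest.approx(mu[k] - 1.959964 * se, abs=1e-4)
            assert hi == pytest.approx(mu[k] + 1.959964 * se, abs=1e-4)

    def test_contains_mle_and_nested_levels(self, medium_fit, medium_adjusted):
        from exosurv.frailty import DEFAULT_BOUNDS
        _, adj = medium_adjusted
        lo95, hi95 = es.profile_ci(adj, 3, 0.95, bounds=DEFAULT_BOUNDS)
        lo90, hi90 = es.profile_ci(adj, 3, 0.90, bounds=DEFAULT_BOUNDS)
        th = medium_fit.theta_hat[3]
        assert lo95 <= th <= hi95
        assert lo95 <= lo90 <= hi90 <= hi95

    def test_open_side_warns_at_search_bounds(self):
        # nearly flat likelihood: the deviance never reaches the quantile
        A = np.array([[1e-9]])
        adj = es.build_adjustment(-A, np.array([[1e9]]), np.zeros(1),
                                  quadratic_loglik(A, np.zeros(1)))
        with pytest.warns(UserWarning, match="one-sided"):
            lo, hi = es.profile_ci(adj, 0, 0.95, bounds=[(-5.0, 5.0)])
        assert lo == -5.0 and hi == 5.0


class TestMaximizeConstrained:
    def test_all_fixed(self):
        f = quadratic_loglik(np.eye(2), np.zeros(2))
        full, val = maximize_constrained(f, np.zeros(2),
                                         fixed={0: 1.0, 1: 2.0})
        np.testing.assert_allclose(full, [1.0, 2.0])
        assert val == pytest.approx(f(np.array([1.0, 2.0])))
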