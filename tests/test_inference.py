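import numpy as np
import pytest
from scipy import integrate, stats

from odesurv.inference import (
    MapFit,
    NormalApprox,
    adaptive_metropolis,
    aic_bic,
    find_map,
    hessian_at,
    laplace_log_marginal,
    normal_approx,
    normal_approx_sample,
)


class TestFindMap:
    def test_quadratic_exact_argmax(self):
        A = np.array([[2.0, 0.5], [0.5, 1.0]])
        b = np.array([1.0, -2.0])
        lp = lambda x: -0.5 * x @ A @ x + b @ x
        fit = find_map(lp, np.zeros(2), gtol=1e-8)
        assert fit.converged
        assert np.allclose(fit.eta, np.linalg.solve(A, b), atol=1e-5)

    def test_exponential_rate_mle(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(0.5, size=300)
        n = t.size
        lp = lambda x: n * x[0] - np.exp(x[0]) * t.sum()  # log-rate parametrisation
        fit = find_map(lp, np.zeros(1), gtol=1e-6)
        assert np.exp(fit.eta[0]) == pytest.approx(n / t.sum(), rel=1e-4)

    def test_hopeless_start_returns_nonconverged(self):
        fit = find_map(lambda x: -np.inf, np.zeros(3), precondition="never")
        assert not fit.converged
        assert fit.logpost == -np.inf


class TestHessian:
    def test_quadratic_recovered_exactly(self):
        A = np.array([[3.0, -1.0, 0.2], [-1.0, 2.0, 0.0], [0.2, 0.0, 1.5]])
        f = lambda x: -0.5 * x @ A @ x
        H = hessian_at(f, np.array([0.3, -0.2, 1.0]))
        assert np.allclose(H, -A, rtol=1e-6, atol=1e-6)

    def test_poisson_style_second_derivative(self):
        # f(x) = k*x - exp(x): f'' = -exp(x)
        k = 7.0
        f = lambda x: k * x[0] - np.exp(x[0])
        H = hessian_at(f, np.array([np.log(k)]))
        assert H[0, 0] == pytest.approx(-k, rel=1e-6)

    def test_exponential_observed_information(self):
        """Constant-hazard model in the rate parametrisation: observed
        information at the MLE is (#events) / rate^2."""
        rng = np.random.default_rng(1)
        t = rng.exponential(1 / 3.0, size=200)
        n = t.size
        loglik = lambda x: n * np.log(x[0]) - x[0] * t.sum()
        rate_mle = n / t.sum()
        H = hessian_at(loglik, np.array([rate_mle]))
        assert -H[0, 0] == pytest.approx(n / rate_mle ** 2, rel=1e-6)

    def test_symmetry(self):
        f = lambda x: -x[0] ** 2 * x[1] - np.sin(x[1] * x[2]) - x[2] ** 4
        H = hessian_at(f, np.array([0.5, 1.0, -0.3]))
        assert np.allclose(H, H.T)


class TestNormalApprox:
    def test_sample_moments_converge(self):
        approx = NormalApprox(mean=np.zeros(3), cov=np.eye(3))
        draws = normal_approx_sample(approx, 100_000, seed=2)
        assert np.allclose(draws.mean(axis=0), 0.0, atol=0.02)
        assert np.allclose(np.cov(draws.T), np.eye(3), atol=0.02)

    def test_zero_draws_empty(self):
        approx = NormalApprox(mean=np.zeros(2), cov=np.eye(2))
        assert normal_approx_sample(approx, 0, seed=0).shape == (0, 2)

    def test_seed_reproducibility(self):
        approx = NormalApprox(mean=np.ones(4), cov=np.diag([1.0, 2.0, 0.5, 1.0]))
        a = normal_approx_sample(approx, 50, seed=9)
        b = normal_approx_sample(approx, 50, seed=9)
        assert np.array_equal(a, b)

    def test_non_spd_rejected(self):
        approx = NormalApprox(mean=np.zeros(2), cov=np.array([[1.0, 0.0], [0.0, -1.0]]))
        with pytest.raises(np.linalg.LinAlgError):
            normal_approx_sample(approx, 10, seed=0)

    def test_from_fit_inverts_hessian(self):
        A = np.array([[4.0, 1.0], [1.0, 2.0]])
        fit = MapFit(eta=np.zeros(2), logpost=0.0, converged=True)
        approx = normal_approx(fit, -A)
        assert np.allclose(approx.cov, np.linalg.inv(A), rtol=1e-10)

    def test_indefinite_hessian_flagged(self):
        fit = MapFit(eta=np.zeros(2), logpost=0.0, converged=True)
        with pytest.raises(np.linalg.LinAlgError):
            normal_approx(fit, np.diag([-1.0, 1.0]))


class TestLaplace:
    def test_conjugate_normal_normal_exact(self):
        """y_i ~ N(theta, s2), theta ~ N(0, tau2): the Laplace approximation
        is exact and matches the analytic marginal."""
        rng = np.random.default_rng(3)
        s2, tau2, n = 0.7, 2.3, 25
        y = rng.normal(1.2, np.sqrt(s2), size=n)

        def logpost(th):
            return float(np.sum(stats.norm.logpdf(y, th[0], np.sqrt(s2)))
                         + stats.norm.logpdf(th[0], 0, np.sqrt(tau2)))

        fit = find_map(logpost, np.zeros(1), gtol=1e-8)
        H = hessian_at(logpost, fit.eta)
        lm = laplace_log_marginal(fit, H)
        # analytic: y ~ N_n(0, s2 I + tau2 11')
        cov = s2 * np.eye(n) + tau2 * np.ones((n, n))
        analytic = stats.multivariate_normal.logpdf(y, mean=np.zeros(n), cov=cov)
        assert lm == pytest.approx(analytic, abs=1e-8)

    def test_exponential_gamma_matches_quadrature(self):
        """1-D exponential-rate likelihood with gamma prior: Laplace log
        marginal matches numerical quadrature to ~1e-3."""
        rng = np.random.default_rng(4)
        # n chosen so the intrinsic Laplace error ~1/(12(n+a)) sits below
        # the 1e-3 comparison tolerance
        t = rng.exponential(0.8, size=150)
        a, b = 2.0, 1.0  # gamma(shape, rate) prior on the rate
        n, S = t.size, t.sum()

        def logpost(x):
            lam = x[0]
            if lam <= 0:
                return -np.inf
            return float(n * np.log(lam) - lam * S + stats.gamma.logpdf(lam, a, scale=1 / b))

        fit = find_map(logpost, np.array([1.0]), gtol=1e-8)
        H = hessian_at(logpost, fit.eta)
        lm = laplace_log_marginal(fit, H)
        shift = fit.logpost  # keep the integrand in floating-point range
        val, _ = integrate.quad(lambda lam: np.exp(logpost([lam]) - shift), 1e-9, 50)
        assert lm == pytest.approx(np.log(val) + shift, abs=1e-3)

    def test_lindley_penalisation(self):
        """Widening the prior drives the marginal likelihood down."""
        y = np.array([0.3, -0.2, 0.5])

        def marginal(tau2):
            def logpost(th):
                return float(np.sum(stats.norm.logpdf(y, th[0], 1.0))
                             + stats.norm.logpdf(th[0], 0, np.sqrt(tau2)))
            fit = find_map(logpost, np.zeros(1), gtol=1e-8)
            return laplace_log_marginal(fit, hessian_at(logpost, fit.eta))

        ms = [marginal(t2) for t2 in (1.0, 100.0, 10000.0)]
        assert ms[0] > ms[1] > ms[2]

    def test_reorder_invariance(self):
        A = np.array([[2.0, 0.3, 0.0], [0.3, 1.0, 0.1], [0.0, 0.1, 3.0]])
        lp = lambda x: -0.5 * x @ A @ x
        perm = [2, 0, 1]
        fit = find_map(lp, np.zeros(3), gtol=1e-8)
        lm1 = laplace_log_marginal(fit, hessian_at(lp, fit.eta))
        Ap = A[np.ix_(perm, perm)]
        lp2 = lambda x: -0.5 * x @ Ap @ x
        fit2 = find_map(lp2, np.zeros(3), gtol=1e-8)
        lm2 = laplace_log_marginal(fit2, hessian_at(lp2, fit2.eta))
        assert lm1 == pytest.approx(lm2, abs=1e-8)

    def test_nonconverged_vetoed(self):
        fit = MapFit(eta=np.zeros(1), logpost=-np.inf, converged=False)
        with pytest.warns(UserWarning):
            assert laplace_log_marginal(fit, -np.eye(1)) == -np.inf


class TestAdaptiveMetropolis:
    def test_recovers_correlated_normal_target(self):
        cov = np.array([[1.0, 0.8], [0.8, 1.0]])
        prec = np.linalg.inv(cov)
        mean = np.array([1.0, -2.0])
        lp = lambda x: -0.5 * (x - mean) @ prec @ (x - mean)
        sample = adaptive_metropolis(lp, np.zeros(2), n_iter=30000, burn_in=5000,
                                     thin=10, seed=11)
        assert 0.1 < sample.acceptance_rate < 0.6
        est_mean = sample.draws.mean(axis=0)
        est_cov = np.cov(sample.draws.T)
        assert np.allclose(est_mean, mean, atol=0.12)
        assert np.allclose(est_cov, cov, atol=0.25)

    def test_symmetric_target_no_skew(self):
        lp = lambda x: -0.5 * float(x @ x)
        sample = adaptive_metropolis(lp, np.zeros(1), n_iter=20000, burn_in=2000,
                                     thin=5, seed=3)
        assert abs(stats.skew(sample.draws[:, 0])) < 0.15

    def test_seed_determinism(self):
        lp = lambda x: -0.5 * float(x @ x)
        a = adaptive_metropolis(lp, np.zeros(2), n_iter=2000, burn_in=500, thin=5, seed=7)
        b = adaptive_metropolis(lp, np.zeros(2), n_iter=2000, burn_in=500, thin=5, seed=7)
        assert np.array_equal(a.draws, b.draws)

    def test_infinite_start_rejected(self):
        with pytest.raises(ValueError):
            adaptive_metropolis(lambda x: -np.inf, np.zeros(1), n_iter=100,
                                burn_in=10, thin=1, seed=0)


class TestInformationCriteria:
    def test_hand_computed_values(self):
        aic, bic = aic_bic(0.0, 2, int(round(np.e ** 2)))
        assert aic == pytest.approx(4.0)
        assert bic == pytest.approx(2 * np.log(round(np.e ** 2)))

    def test_monotone_in_k_at_fixed_loglik(self):
        a1, b1 = aic_bic(-100.0, 3, 50)
        a2, b2 = aic_bic(-100.0, 5, 50)
        assert a2 > a1 and b2 > b1

    def test_exponential_toy(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(2.0, 100)
        rate = 100 / t.sum()
        ll = 100 * np.log(rate) - rate * t.sum()
        aic, bic = aic_bic(ll, 1, 100)
        assert aic == pytest.approx(2 - 2 * ll)
        assert bic == pytest.approx(np.log(100) - 2 * ll)
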