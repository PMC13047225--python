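import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from odesurv.likelihood import (
    PriorSpec,
    SurvivalDataset,
    complexity_log_prior,
    g_effective_sample_size,
    log_likelihood,
    log_posterior,
    log_prior,
)
from odesurv.mapping import InclusionPattern, PredictorSpec
from odesurv.systems import LOGISTIC, HAZARD_RESPONSE


def constant_hazard_spec(c):
    """Logistic system with h0 = kappa = c is a constant-hazard model."""
    return PredictorSpec(system=LOGISTIC, covariates={}, fixed={"h0": c})


class TestSurvivalDataset:
    def test_valid_construction(self, toy_dataset):
        assert toy_dataset.n == 3
        assert toy_dataset.n_events == 2
        assert toy_dataset.n_censored == 1

    @pytest.mark.parametrize("time,delta", [
        ([0.0, 1.0], [1, 1]),        # nonpositive time
        ([1.0, 2.0], [1, 2]),        # non-binary status
        ([1.0, np.nan], [1, 1]),     # missing time
    ])
    def test_invalid_rejected(self, time, delta):
        with pytest.raises(ValueError):
            SurvivalDataset(np.array(time), np.array(delta),
                            pd.DataFrame({"x": [0.0] * len(time)}))


class TestLogLikelihood:
    def test_exponential_event_closed_form(self):
        """Constant hazard c: one subject with t=1, delta=1 -> log c - c."""
        c = 2.0
        spec = constant_hazard_spec(c)
        data = SurvivalDataset([1.0], [1], pd.DataFrame(index=[0]))
        eta = np.array([0.0, np.log(c)])  # lam irrelevant, kappa = c
        ll = log_likelihood(eta, spec, data)
        assert ll == pytest.approx(np.log(2) - 2, abs=1e-6)
        assert ll == pytest.approx(-1.30685, abs=1e-4)

    def test_exponential_censored_closed_form(self):
        c = 2.0
        spec = constant_hazard_spec(c)
        data = SurvivalDataset([1.0], [0], pd.DataFrame(index=[0]))
        ll = log_likelihood(np.array([0.0, np.log(c)]), spec, data)
        assert ll == pytest.approx(-2.0, abs=1e-6)

    def test_short_censored_followup_contributes_nothing(self):
        spec = constant_hazard_spec(1.0)
        data = SurvivalDataset([1e-9] * 5, [0] * 5, pd.DataFrame(index=range(5)))
        assert log_likelihood(np.array([0.0, 0.0]), spec, data) == pytest.approx(0.0, abs=1e-6)

    def test_density_survival_identity(self, recovery_replicate):
        """sum delta log h - sum H == sum delta log f + sum (1-delta) log S."""
        data, truth = recovery_replicate
        from odesurv.mapping import individual_parameters
        from odesurv.solver import solve_ensemble

        eta, spec = truth["eta"], truth["spec"]
        ll = log_likelihood(eta, spec, data)
        theta = individual_parameters(eta, spec, data.X)
        ev = solve_ensemble(spec.system, theta, data.time, fixed=spec.fixed_constants())
        log_f = np.log(ev.h) - ev.H
        log_S = -ev.H
        alt = float(np.sum(data.delta * log_f) + np.sum((1 - data.delta) * log_S))
        assert ll == pytest.approx(alt, abs=1e-8)

    def test_subject_order_invariance(self, small_replicate):
        data, truth = small_replicate
        ll = log_likelihood(truth["eta"], truth["spec"], data)
        rng = np.random.default_rng(0)
        perm = rng.permutation(data.n)
        data_p = SurvivalDataset(data.time[perm], data.delta[perm],
                                 data.X.iloc[perm].reset_index(drop=True))
        ll_p = log_likelihood(truth["eta"], truth["spec"], data_p)
        assert ll_p == pytest.approx(ll, abs=1e-8)

    def test_closed_form_and_numeric_paths_agree(self):
        """Logistic likelihood via the ODE solver matches direct closed-form
        evaluation on random problems."""
        from odesurv.systems import logistic_cumhaz, logistic_hazard, LogisticParams

        rng = np.random.default_rng(5)
        spec = PredictorSpec(system=LOGISTIC, covariates={"lam": ("x",), "kappa": ("x",)},
                             fixed={"h0": 0.1})
        for _ in range(5):
            n = 40
            X = pd.DataFrame({"x": rng.integers(0, 2, n).astype(float)})
            t = rng.uniform(0.1, 3.0, n)
            d = rng.integers(0, 2, n)
            data = SurvivalDataset(t, d, X)
            eta = rng.normal(0, 0.5, size=4)
            ll = log_likelihood(eta, spec, data)
            ll_closed = 0.0
            for i in range(n):
                lam = np.exp(eta[0] + eta[1] * X.x[i])
                kap = np.exp(eta[2] + eta[3] * X.x[i])
                p = LogisticParams(lam=lam, kappa=kap, h0=0.1)
                ll_closed += d[i] * np.log(logistic_hazard(t[i], p)) - logistic_cumhaz(t[i], p)
            assert ll == pytest.approx(ll_closed, abs=1e-5)

    def test_solver_failure_gives_neg_inf(self):
        spec = PredictorSpec(system=LOGISTIC, covariates={})
        data = SurvivalDataset([5.0], [1], pd.DataFrame(index=[0]))
        assert log_likelihood(np.array([34.0, 0.0]), spec, data) == -np.inf


class TestPriors:
    def test_intercept_only_normal_density(self):
        spec = PredictorSpec(system=HAZARD_RESPONSE, covariates={})
        prior = PriorSpec(intercept_variance=10.0)
        lp = log_prior(np.zeros(4), spec, prior)
        assert lp == pytest.approx(4 * stats.norm.logpdf(0, 0, np.sqrt(10)))

    def test_gprior_orthonormal_reduces_to_iid(self):
        n = 64
        rng = np.random.default_rng(0)
        Q, _ = np.linalg.qr(rng.normal(size=(n, 2)))
        X = pd.DataFrame({"a": Q[:, 0], "b": Q[:, 1]})
        spec = PredictorSpec(system=LOGISTIC, covariates={"lam": ("a", "b")})
        prior = PriorSpec(coef_mode="gprior", g={"lam": 4.0})
        data = SurvivalDataset(np.ones(n), np.ones(n), X)
        lp = log_prior(np.zeros(4), spec, prior, data)
        expected = 2 * stats.norm.logpdf(0, 0, np.sqrt(10)) \
            + stats.multivariate_normal.logpdf([0, 0], cov=4 * np.eye(2))
        assert lp == pytest.approx(expected, rel=1e-10)

    def test_gprior_density_normalised(self):
        """g-prior block density integrates to 1 (2-D quadrature)."""
        rng = np.random.default_rng(1)
        Xm = rng.normal(size=(30, 2))
        X = pd.DataFrame({"a": Xm[:, 0], "b": Xm[:, 1]})
        spec = PredictorSpec(system=LOGISTIC, covariates={"lam": ("a", "b")})
        prior = PriorSpec(coef_mode="gprior", g={"lam": 2.0})
        data = SurvivalDataset(np.ones(30), np.ones(30), X)
        intercepts = 2 * float(stats.norm.logpdf(0, 0, np.sqrt(10)))

        def dens(b2, b1):
            eta = np.array([0.0, b1, b2, 0.0])
            return np.exp(log_prior(eta, spec, prior, data) - intercepts)

        val, _ = integrate.dblquad(dens, -3, 3, -3, 3, epsabs=1e-6)
        assert val == pytest.approx(1.0, abs=1e-3)

    def test_collinear_design_rejected(self):
        X = pd.DataFrame({"a": np.ones(10), "b": np.ones(10)})
        spec = PredictorSpec(system=LOGISTIC, covariates={"lam": ("a", "b")})
        prior = PriorSpec(coef_mode="gprior", g={"lam": 1.0})
        data = SurvivalDataset(np.ones(10), np.ones(10), X)
        with pytest.raises(np.linalg.LinAlgError, match="lam"):
            log_prior(np.zeros(4), spec, prior, data)

    def test_h0_gamma_prior_with_jacobian(self):
        spec = PredictorSpec(system=LOGISTIC, covariates={}, free_initials=("h0",))
        prior = PriorSpec(h0_gamma=(2.0, 0.5))
        eta = np.array([0.0, 0.0, np.log(0.8)])
        lp = log_prior(eta, spec, prior)
        expected = 2 * stats.norm.logpdf(0, 0, np.sqrt(10)) \
            + stats.gamma.logpdf(0.8, 2.0, scale=2.0) + np.log(0.8)
        assert lp == pytest.approx(expected, rel=1e-10)

    def test_effective_sample_size_rule(self):
        assert g_effective_sample_size(2939, 1410) == pytest.approx(2939 - 705.0)
        assert g_effective_sample_size(100, 40, divisor=100) == pytest.approx(0.8)


class TestComplexityPrior:
    def test_uniform_at_C_zero(self):
        assert complexity_log_prior(5, d_tilde=16, C=0.0) == 0.0

    def test_one_variable_increment(self):
        d, C = 16, 0.1
        assert complexity_log_prior(6, d, C) - complexity_log_prior(5, d, C) \
            == pytest.approx(-C * np.log(d))

    def test_prior_odds_of_large_models(self):
        """|gamma|=11 vs |gamma|=1 at C=0.1 has prior odds d~^{-1}."""
        d = 16
        diff = complexity_log_prior(11, d, 0.1) - complexity_log_prior(1, d, 0.1)
        assert np.exp(diff) == pytest.approx(1 / d)

    def test_accepts_inclusion_pattern(self):
        spec = PredictorSpec(system=LOGISTIC, covariates={"lam": ("a",), "kappa": ("b",)})
        gamma = InclusionPattern.all_ones(spec)
        assert complexity_log_prior(gamma, 4, 0.5) == pytest.approx(-0.5 * 2 * np.log(4))


class TestLogPosterior:
    def test_flat_prior_mode_equals_mle(self):
        """With a huge prior variance the posterior mode is the MLE; for an
        exponential model the MLE rate is events / total time."""
        from odesurv.inference import find_map

        rng = np.random.default_rng(2)
        t = rng.exponential(1 / 1.7, size=200)
        data = SurvivalDataset(t, np.ones(200, dtype=int), pd.DataFrame(index=range(200)))
        spec = PredictorSpec(system=LOGISTIC, covariates={}, fixed={"h0": 1.0})

        # tie kappa to h0 via solving with h0 == kappa is not expressible with
        # a fixed h0; instead use a free initial so that h0 == kappa at the
        # optimum is approximated by a long-run constant hazard; simpler: use
        # the closed-form identity below on the kappa-only direction.
        def lp(eta):
            # constant hazard c: set lam arbitrary, kappa=c, h0=c via fixed
            c = float(np.exp(eta[0]))
            sp = PredictorSpec(system=LOGISTIC, covariates={}, fixed={"h0": c})
            full = np.array([0.0, eta[0]])
            return log_posterior(full, sp, data, PriorSpec(intercept_variance=1e8))

        fit = find_map(lp, np.array([0.0]), gtol=1e-4)
        rate_hat = np.exp(fit.eta[0])
        assert rate_hat == pytest.approx(200 / t.sum(), rel=1e-3)

    def test_prior_only_mode_at_zero(self):
        spec = PredictorSpec(system=HAZARD_RESPONSE, covariates={})
        prior = PriorSpec()
        lp0 = log_prior(np.zeros(4), spec, prior)
        for shift in np.eye(4):
            assert log_prior(shift, spec, prior) < lp0

    def test_finite_at_truth_on_scenario(self, small_replicate):
        data, truth = small_replicate
        lp = log_posterior(truth["eta"], truth["spec"], data, PriorSpec())
        assert np.isfinite(lp)

    def test_neg_inf_propagates(self):
        spec = PredictorSpec(system=LOGISTIC, covariates={})
        data = SurvivalDataset([5.0], [1], pd.DataFrame(index=[0]))
        assert log_posterior(np.array([34.0, 0.0]), spec, data, PriorSpec()) == -np.inf
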