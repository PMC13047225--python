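import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

from odesurv.systems import (
    HAZARD_RESPONSE,
    AttractorReport,
    HazardResponseParams,
    LogisticParams,
    OdeHazardSystem,
    classify_attractor,
    get_system,
    hazard_response_rhs,
    logistic_cumhaz,
    logistic_hazard,
    register_system,
)

E = np.e


class TestLogisticClosedForm:
    def test_initial_condition(self):
        p = LogisticParams(lam=0.7, kappa=3.0, h0=0.2)
        assert logistic_hazard(0.0, p) == pytest.approx(0.2)
        assert logistic_cumhaz(0.0, p) == pytest.approx(0.0)

    def test_fixed_point_constant_hazard(self):
        p = LogisticParams(lam=1.3, kappa=2.0, h0=2.0)
        t = np.linspace(0, 5, 7)
        assert np.allclose(logistic_hazard(t, p), 2.0)
        assert np.allclose(logistic_cumhaz(t, p), 2.0 * t)

    def test_reference_values(self):
        p = LogisticParams(lam=1.0, kappa=2.0, h0=1.0)
        assert logistic_hazard(1.0, p) == pytest.approx(2 * E / (1 + E), rel=1e-12)
        assert logistic_cumhaz(1.0, p) == pytest.approx(2 * np.log((1 + E) / 2), rel=1e-12)

    def test_no_overflow_for_large_lambda_t(self):
        p = LogisticParams(lam=50.0, kappa=2.0, h0=0.01)
        h = logistic_hazard(np.array([50.0, 500.0]), p)
        H = logistic_cumhaz(np.array([50.0, 500.0]), p)
        assert np.isfinite(h).all() and np.isfinite(H).all()
        assert h == pytest.approx([2.0, 2.0])

    @pytest.mark.parametrize("lam,kappa,h0", [
        (0.01, 0.1, 0.05), (0.1, 10.0, 0.5), (1.0, 1.0, 2.0), (10.0, 0.01, 0.001),
    ])
    def test_matches_numerical_integration_4_decades(self, lam, kappa, h0):
        """Closed form equals a numerical solve of the logistic ODE."""
        p = LogisticParams(lam=lam, kappa=kappa, h0=h0)
        t_grid = np.linspace(0.0, 3.0 / lam, 20)
        sol = solve_ivp(
            lambda t, y: [lam * y[0] * (1 - y[0] / kappa), y[0]],
            (0, t_grid[-1]), [h0, 0.0], t_eval=t_grid, rtol=1e-10, atol=1e-12,
        )
        assert np.allclose(sol.y[0], logistic_hazard(t_grid, p), rtol=1e-6)
        assert np.allclose(sol.y[1], logistic_cumhaz(t_grid, p), rtol=1e-6, atol=1e-10)

    def test_cumhaz_is_integral_of_hazard(self):
        p = LogisticParams(lam=0.8, kappa=1.5, h0=0.3)
        val, _ = quad(lambda t: logistic_hazard(t, p), 0, 2.0)
        assert logistic_cumhaz(2.0, p) == pytest.approx(val, rel=1e-8)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        lam=st.floats(0.05, 20), kappa=st.floats(0.05, 20), h0=st.floats(0.05, 20),
        t=st.floats(0.0, 10.0),
    )
    def test_bounded_and_monotone(self, lam, kappa, h0, t):
        p = LogisticParams(lam=lam, kappa=kappa, h0=h0)
        h = float(logistic_hazard(t, p))
        assert min(h0, kappa) - 1e-12 <= h <= max(h0, kappa) + 1e-12
        h_later = float(logistic_hazard(t + 0.5, p))
        if h0 < kappa:
            assert h_later >= h - 1e-12
        else:
            assert h_later <= h + 1e-12

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            LogisticParams(lam=-1.0, kappa=1.0, h0=1.0)
        with pytest.raises(ValueError):
            LogisticParams(lam=1.0, kappa=np.inf, h0=1.0)


class TestHazardResponseRhs:
    def test_extinction_fixed_point(self):
        p = HazardResponseParams(lam=1, kappa=1, alpha=0.5, mu=1, h0=0.1, q0=0.1)
        assert hazard_response_rhs((0.0, 0.0), p) == (0.0, 0.0)

    def test_decouples_at_alpha_zero(self):
        p = HazardResponseParams(lam=1.2, kappa=2.0, alpha=0.0, mu=0.7, h0=0.1, q0=0.1)
        h, q = 0.4, 0.9
        dh, dq = hazard_response_rhs((h, q), p)
        assert dh == pytest.approx(1.2 * h * (1 - h / 2.0))
        assert dq == pytest.approx(0.7 * q * (1 - q / 2.0))

    def test_interior_equilibrium(self):
        p = HazardResponseParams(lam=1, kappa=1, alpha=0.5, mu=1, h0=0.1, q0=0.1)
        dh, dq = hazard_response_rhs((2 / 3, 2 / 3), p)
        assert dh == pytest.approx(0.0, abs=1e-14)
        assert dq == pytest.approx(0.0, abs=1e-14)

    def test_axes_invariant(self):
        p = HazardResponseParams(lam=2, kappa=1.5, alpha=1.0, mu=3, h0=0.1, q0=0.1)
        assert hazard_response_rhs((0.0, 0.7), p)[0] == 0.0
        assert hazard_response_rhs((0.7, 0.0), p)[1] == 0.0


class TestClassifyAttractor:
    def test_no_competition_is_hazard_wins(self):
        p = HazardResponseParams(lam=1, kappa=2.5, alpha=0.0, mu=1, h0=0.1, q0=0.1)
        rep = classify_attractor(p)
        assert rep.regime == "hazard_wins"
        assert rep.h_star == pytest.approx(2.5)
        assert rep.d_det == pytest.approx(1.0)

    def test_coexistence_example(self):
        p = HazardResponseParams(lam=1, kappa=1, alpha=0.5, mu=1, h0=0.1, q0=0.1)
        rep = classify_attractor(p)
        assert rep.regime == "coexistence" and rep.stable
        assert rep.d_det == pytest.approx(0.75)
        assert rep.h_star == pytest.approx(2 / 3)
        assert rep.q_star == pytest.approx(2 / 3)

    def test_bistable_saddle_flagged(self):
        # alpha*kappa > max(lam, mu): both boundary equilibria stable
        p = HazardResponseParams(lam=1, kappa=1, alpha=3.0, mu=1, h0=0.1, q0=0.1)
        rep = classify_attractor(p)
        assert rep.regime == "coexistence" and not rep.stable
        assert rep.d_det < 0 and rep.h_star > 0 and rep.q_star > 0

    def test_response_wins_when_competition_beats_hazard_growth(self):
        # lam < alpha*kappa < mu: only the (0, kappa) equilibrium is stable;
        # verified by long-horizon integration (h -> 0, q -> kappa)
        p = HazardResponseParams(lam=1, kappa=1, alpha=1.5, mu=2, h0=0.1, q0=0.1)
        rep = classify_attractor(p)
        assert rep.regime == "response_wins"
        assert rep.q_star == pytest.approx(-2.0)
        assert rep.d_det == pytest.approx(-0.125)
        sol = solve_ivp(
            lambda t, y: hazard_response_rhs(y, p), (0, 200), [0.1, 0.1],
            rtol=1e-9, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(0.0, abs=1e-6)
        assert sol.y[1, -1] == pytest.approx(1.0, abs=1e-6)

    def test_hazard_wins_mirror_case(self):
        p = HazardResponseParams(lam=2, kappa=1, alpha=1.5, mu=1, h0=0.1, q0=0.1)
        rep = classify_attractor(p)
        assert rep.regime == "hazard_wins"
        sol = solve_ivp(
            lambda t, y: hazard_response_rhs(y, p), (0, 200), [0.1, 0.1],
            rtol=1e-9, atol=1e-12,
        )
        assert sol.y[0, -1] == pytest.approx(1.0, abs=1e-6)

    def test_degenerate_boundary(self):
        # alpha*kappa == lam == mu: D = 0
        p = HazardResponseParams(lam=1, kappa=1, alpha=1.0, mu=1, h0=0.1, q0=0.1)
        with pytest.warns(UserWarning):
            rep = classify_attractor(p)
        assert rep.regime == "degenerate"


class TestRegistry:
    def test_builtin_lookup(self):
        assert get_system("logistic").state_dim == 1
        assert get_system("hazard_response").state_dim == 2
        with pytest.raises(KeyError):
            get_system("gompertz")

    def test_user_registered_system(self):
        sys = OdeHazardSystem(
            name="constant", state_dim=1, parameter_names=("c",), positive=(True,),
            rhs=lambda y, theta: np.zeros_like(np.atleast_1d(y[..., 0]))[..., None],
            initial_state=lambda theta, fixed: np.atleast_1d(theta[..., 0]),
        )
        register_system(sys)
        assert get_system("constant") is sys
        with pytest.raises(ValueError):
            register_system(sys)

    def test_invalid_state_dim(self):
        with pytest.raises(ValueError):
            OdeHazardSystem(
                name="bad", state_dim=0, parameter_names=(), positive=(),
                rhs=lambda y, th: y, initial_state=lambda th, f: th,
            )
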