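"""Closed-form small-|kappa| solutions and the cosh-mode closure."""

import numpy as np
import pytest

from scaffoldwave import (
    L_infinity,
    L_largeT,
    L_smallkappa,
    alpha_beta,
    fit_m,
    general_ic_forms,
    integrate_AB,
    interior_layer_f,
    n_smallkappa,
    solve_L_implicit,
    transform_time,
)
from scaffoldwave.asymptotics import AB_from_L, N_profile, closure_residual

SQRT2 = np.sqrt(2.0)


@pytest.fixture(scope="module")
def ap():
    return alpha_beta(0.05, 0.01)


class TestTransformTime:
    def test_marginal_case_is_identity(self):
        t = np.array([0.0, 1.0, 500.0])
        np.testing.assert_array_equal(transform_time(t, 0.0), t)

    def test_small_kappa_matches_series(self):
        # near kappa = 0 the transform is t(1 + kappa t/2 + ...)
        t = 10.0
        k = 1e-9
        assert transform_time(t, k) == pytest.approx(t * (1 + k * t / 2), rel=1e-12)

    def test_direct_value(self):
        assert transform_time(1000.0, 0.001) == pytest.approx((np.e - 1) / 0.001, rel=1e-12)

    def test_decay_saturates(self):
        assert transform_time(1e7, -0.001) == pytest.approx(1000.0, rel=1e-9)


class TestAlphaBeta:
    def test_reference_amplitudes(self, ap):
        assert ap.alpha == pytest.approx(2e4 * 0.0024**1.5, rel=1e-12)
        assert ap.L0 == pytest.approx(SQRT2 * np.arccosh(5.0), rel=1e-12)
        # sinh(2 u) = 2 sinh u cosh u with u = acosh(5): beta = 10 sqrt(24) - 2u
        assert ap.beta == pytest.approx(10 * np.sqrt(24) - 2 * np.arccosh(5.0), rel=1e-10)

    def test_front_round_trip(self):
        L0 = 2.7
        B0 = 0.01
        A0 = B0 * np.cosh(L0 / SQRT2)
        assert alpha_beta(A0, B0).L0 == pytest.approx(L0, rel=1e-12)

    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            alpha_beta(0.01, 0.05)


class TestImplicitFront:
    def test_initial_time_returns_L0(self, ap):
        assert solve_L_implicit(0.0, ap) == pytest.approx(ap.L0, rel=1e-10)

    def test_reference_value(self, ap):
        assert solve_L_implicit(1e4, ap) == pytest.approx(7.6091, abs=2e-4)

    def test_large_T_expansion_consistency(self, ap):
        assert L_largeT(1e4, ap) == pytest.approx(7.6078, abs=2e-4)
        for T in (1e4, 1e6, 1e8):
            rel = abs(L_largeT(T, ap) - solve_L_implicit(T, ap)) / solve_L_implicit(T, ap)
            assert rel < 1e-3
        assert L_largeT(1e8, ap) / solve_L_implicit(1e8, ap) == pytest.approx(1.0, abs=1e-5)

    def test_expansion_domain_guard(self, ap):
        with pytest.raises(ValueError):
            L_largeT(1e-6, ap)

    def test_log_slope_is_inverse_sqrt2(self, ap):
        T = np.geomspace(1e6, 1e8, 40)
        slope = np.polyfit(np.log(T), L_largeT(T, ap), 1)[0]
        assert slope == pytest.approx(1 / SQRT2, rel=2e-3)


class TestCoshClosure:
    def test_profile_vanishes_at_front(self, ap):
        L = solve_L_implicit(100.0, ap)
        assert N_profile(L, L, ap) == pytest.approx(0.0, abs=1e-15)
        x = np.linspace(0, L, 50)
        N = N_profile(x, L, ap)
        assert np.argmax(N) == 0
        assert np.all(np.diff(N) < 0)

    def test_closure_is_exact(self, ap):
        """The implicit (A, B) pair satisfies the planar amplitude ODEs to
        rounding: the cosh ansatz is an exact reduction, not an approximation."""
        T = np.geomspace(1e-3, 1e4, 200)
        rA, rB = closure_residual(T, ap)
        assert np.max(np.abs(rA)) < 1e-12
        assert np.max(np.abs(rB)) < 1e-12

    def test_numerical_amplitudes_match_implicit_solution(self, ap):
        T_eval = np.array([0.0, 1.0, 10.0, 100.0, 1000.0])
        state = integrate_AB(0.05, 0.01, 1000.0, T_eval=T_eval)
        L = np.array([solve_L_implicit(T, ap) for T in T_eval])
        A, B = AB_from_L(L, ap)
        np.testing.assert_allclose(state.A, A, rtol=1e-7)
        np.testing.assert_allclose(state.B, B, rtol=1e-7)
        assert np.all(state.B < state.A)
        assert np.all(np.diff(state.A) < 0) and np.all(np.diff(state.B) < 0)

    def test_pure_decay_limit(self):
        # B0 -> 0: A obeys dA/dT = -A^2, A = A0/(1 + A0 T)
        state = integrate_AB(0.05, 1e-10, 200.0, T_eval=np.array([0.0, 50.0, 200.0]))
        np.testing.assert_allclose(state.A, 0.05 / (1 + 0.05 * state.T), rtol=1e-6)


class TestLargeTimeFront:
    def test_growth_speed_limit(self, ap):
        # 0 < kappa << 1: L ~ kappa t / sqrt(2) at large t
        k = 1e-3
        t = 1e7
        assert L_smallkappa(t, k, ap) / t == pytest.approx(k / SQRT2, rel=1e-2)

    def test_decay_approaches_stationary_front(self, ap):
        k = -1e-3
        assert L_smallkappa(1e7, k, ap) == pytest.approx(
            L_infinity(k, ap.alpha), rel=1e-9
        )

    def test_marginal_limit_recovers_largeT(self, ap):
        t = 5e3
        assert L_smallkappa(t, 1e-12, ap) == pytest.approx(L_largeT(t, ap), rel=1e-8)

    def test_stationary_front_value(self, ap):
        assert L_infinity(-0.001, ap.alpha) == pytest.approx(5.9818, abs=2e-4)

    def test_stationary_front_shrinks_with_faster_death(self, ap):
        Ls = [L_infinity(k, ap.alpha) for k in (-1e-4, -1e-3, -1e-2)]
        assert np.all(np.diff(Ls) < 0)

    def test_stationary_front_sign_guard(self, ap):
        with pytest.raises(ValueError):
            L_infinity(0.001, ap.alpha)


class TestCellProfiles:
    def test_growth_saturates_at_kappa(self, ap):
        k = 1e-3
        assert n_smallkappa(0.0, 1e7, k, ap) == pytest.approx(k, rel=1e-6)

    def test_decay_envelope(self, ap):
        k = -1e-3
        t = np.array([5e3, 1e4, 2e4])
        vals = n_smallkappa(0.0, t, k, ap)
        # amplitude decays like e^{-|kappa| t}
        ratios = vals[1:] / vals[:-1]
        expected = np.exp(k * np.diff(t))
        np.testing.assert_allclose(ratios, expected, rtol=0.05)

    def test_marginal_routes_to_general_form(self, ap):
        x = np.linspace(0, 3, 7)
        t = 1e4
        m = np.sqrt(2 / ap.alpha)
        N, _ = general_ic_forms(t, m, x=x)
        np.testing.assert_allclose(n_smallkappa(x, t, 0.0, ap), N, rtol=1e-12)


class TestInteriorLayer:
    def test_edge_and_half_depth(self):
        assert interior_layer_f(0.0) == 0.0
        assert interior_layer_f(-SQRT2 * np.log(2)) == pytest.approx(0.5)
        theta = -np.linspace(0, 20, 100)
        f = interior_layer_f(theta)
        assert np.all(np.diff(f[np.argsort(theta)]) <= 0)
        assert interior_layer_f(-40.0) == pytest.approx(1.0)

    def test_layer_ode_residual_vanishes(self):
        # -b f' = (f f')' + f(1-f) holds identically for f = 1 - e^{theta/sqrt2}
        theta = -np.linspace(1e-3, 10, 400)
        E = np.exp(theta / SQRT2)
        f = 1 - E
        fp = -E / SQRT2
        ffp_p = -(E - 2 * E**2) / 2.0  # d/dtheta of (f f')
        resid = (1 / SQRT2) * fp + ffp_p + f * (1 - f)
        assert np.max(np.abs(resid)) < 1e-14


class TestGeneralInitialData:
    def test_reduces_to_cosh_ansatz_large_T(self, ap):
        m = np.sqrt(2 / ap.alpha)
        T = 1e6
        x = np.linspace(0, 5, 11)
        N, L = general_ic_forms(T, m, x=x)
        expected = 1 / T - np.sqrt(2 / ap.alpha) * np.cosh(x / SQRT2) * T**-1.5
        np.testing.assert_allclose(N, expected, rtol=1e-12)
        assert L == pytest.approx(solve_L_implicit(T, ap), rel=2e-3)

    def test_front_offset_between_two_m(self):
        T = 1e8
        _, L1 = general_ic_forms(T, 0.5)
        _, L2 = general_ic_forms(T, 1.5)
        assert L1 - L2 == pytest.approx(SQRT2 * np.log(1.5 / 0.5), rel=1e-3)

    def test_domain_guard(self):
        with pytest.raises(ValueError):
            general_ic_forms(0.5, 1.0)


class TestFitM:
    def test_recovers_generating_constant(self):
        T = np.geomspace(1e2, 1e4, 200)
        m_true = 0.9
        L = np.array([general_ic_forms(Ti, m_true)[1] for Ti in T])
        m, resid = fit_m((T, L), tail_fraction=0.99)
        assert m == pytest.approx(m_true, rel=5e-3)
        assert resid < 1e-12

    def test_warns_on_short_tail(self):
        T = np.linspace(900, 1000, 10)
        L = np.array([general_ic_forms(Ti, 0.9)[1] for Ti in T])
        with pytest.warns(UserWarning, match="tail"):
            fit_m((T, L), tail_fraction=0.5)
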