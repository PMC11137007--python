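import math

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings
from hypothesis import strategies as st

from leafopt import (
    DomainError,
    RateFunction,
    RateSet,
    SeasonParams,
    SolverSettings,
    costate_rhs,
    evaluate_objective,
    hamiltonian,
    optimal_control,
    solve,
    solve_backward,
    solve_forward,
)

from tests.conftest import N_TEST


def const_rates(p=1.0, h=2.0, b=2.0, u=1e-4):
    return RateSet(
        p=RateFunction.constant(p),
        h=RateFunction.constant(h),
        b_eff=RateFunction.constant(b),
        u=u,
    )


class TestOptimalControl:
    def test_below_threshold_is_zero(self, fig2_rates):
        # lam <= 1/(b h) = 0.25
        assert optimal_control(0.2, 0.3, fig2_rates, 1.0) == 0.0

    def test_interior_matches_grid_argmax(self, fig2_rates):
        s_hat = optimal_control(1.0, 0.3, fig2_rates, 1.0)
        assert s_hat == pytest.approx(0.5, rel=1e-12)
        grid = np.linspace(0.0, 1.0, 100_001)  # 1e-5 resolution
        H = hamiltonian(1.0, 1.0, 0.3, grid, fig2_rates)
        assert abs(grid[np.argmax(H)] - s_hat) <= 2e-5

    def test_saturation(self, fig2_rates):
        assert optimal_control(10.0, 0.3, fig2_rates, 0.132) == 0.132

    def test_exact_threshold_tie_goes_to_zero(self, fig2_rates):
        # lam * b * h == 1 exactly
        assert optimal_control(0.25, 0.3, fig2_rates, 1.0) == 0.0

    def test_zero_benefit_returns_zero(self):
        rates = const_rates(h=0.0)
        assert optimal_control(5.0, 0.3, rates, 1.0) == 0.0

    def test_vectorized_matches_scalar(self, fig2_rates, rng):
        lam = rng.uniform(0.0, 3.0, 64)
        t = rng.uniform(0.0, 1.0, 64)
        vec = optimal_control(lam, t, fig2_rates, 0.132)
        scal = [optimal_control(l, x, fig2_rates, 0.132) for l, x in zip(lam, t)]
        np.testing.assert_allclose(vec, scal, rtol=1e-14)

    @given(lam=st.floats(0.0, 5.0), t=st.floats(0.0, 1.0),
           s_max=st.floats(0.01, 2.0))
    @hyp_settings(max_examples=100, deadline=None)
    def test_hamiltonian_maximizer_property(self, lam, t, s_max):
        rates = const_rates()
        s_hat = optimal_control(lam, t, rates, s_max)
        assert 0.0 <= s_hat <= s_max
        grid = np.linspace(0.0, s_max, 1001)
        H_grid = hamiltonian(1.0, lam, t, grid, rates)
        H_hat = hamiltonian(1.0, lam, t, s_hat, rates)
        assert H_hat >= np.max(H_grid) - 1e-10


class TestCostateRhs:
    def test_terminal_slope_is_minus_p(self, fig2_rates):
        # lam = 0 forces s = 0, so dlam/dt = -p
        assert costate_rhs(0.0, 0.3, fig2_rates, 0.132) == pytest.approx(-1.0)

    def test_stationary_point(self):
        # p=1, u=0, h=2, b=2: the interior stationary point of the costate
        # equation is lam=0.5625 (s_hat=0.25, 1+bs=1.5):
        # -(1 - 0.25) + 0.5625*(0 + 2/1.5) = 0
        rates = const_rates(u=0.0)
        assert optimal_control(0.5625, 0.3, rates, 1.0) == pytest.approx(0.25)
        assert costate_rhs(0.5625, 0.3, rates, 1.0) == pytest.approx(0.0, abs=1e-14)

    def test_zero_production_band(self, fig2_rates):
        lam = 0.2  # below 1/(bh)
        expected = -1.0 + lam * 2.0001
        assert costate_rhs(lam, 0.3, fig2_rates, 0.132) == pytest.approx(expected)


class TestSolveBackward:
    def test_zero_phase_closed_form(self, fig2_rates, fig2_params, settings):
        t, lam, s = solve_backward(fig2_rates, fig2_params, settings)
        assert lam[-1] == 0.0
        a = 2.0001
        # closed form for the terminal s=0 phase of the costate equation
        zero_phase = t > 0.66
        expected = (1.0 - np.exp(-a * (1.0 - t[zero_phase]))) / a
        np.testing.assert_allclose(lam[zero_phase], expected, rtol=1e-7)
        assert np.all(s[zero_phase] == 0.0)

    def test_no_photosynthesis_no_value(self, settings):
        rates = const_rates(p=0.0)
        params = SeasonParams(s_max=0.132, n_steps=N_TEST)
        t, lam, s = solve_backward(rates, params, settings)
        np.testing.assert_allclose(lam, 0.0, atol=1e-14)
        np.testing.assert_allclose(s, 0.0, atol=1e-14)

    def test_three_ordered_phases(self, fig2_traj):
        s = fig2_traj.s
        i_max = np.flatnonzero(s >= 0.132 * (1 - 1e-9))
        i_int = np.flatnonzero((s > 1e-12) & (s < 0.132 * (1 - 1e-9)))
        i_zero = np.flatnonzero(s <= 1e-12)
        assert len(i_max) and len(i_int) and len(i_zero)
        assert i_max.max() < i_int.min() < i_zero[i_zero > i_int.max()].min()

    def test_lambda_continuous(self, fig2_traj):
        jumps = np.abs(np.diff(fig2_traj.lam))
        assert jumps.max() < 5.0 / N_TEST  # bounded slope ~ |p| + lam*(u+h)


class TestSolveForward:
    def test_zero_schedule_exponential_decay(self, fig2_rates, fig2_params, settings):
        L = solve_forward(0.0, fig2_rates, fig2_params, settings)
        t = np.linspace(0, 1, N_TEST + 1)
        np.testing.assert_allclose(L, np.exp(-2.0001 * t), rtol=1e-10)

    def test_full_schedule_constant_coefficient(self, fig2_rates, fig2_params, settings):
        s_max = fig2_params.s_max
        L = solve_forward(s_max, fig2_rates, fig2_params, settings)
        t = np.linspace(0, 1, N_TEST + 1)
        rate = 1e-4 + 2.0 / (1.0 + 2.0 * s_max)
        np.testing.assert_allclose(L, np.exp(-rate * t), rtol=1e-10)

    def test_tiny_L0_scales(self, fig2_rates, settings):
        params = SeasonParams(L0=1e-8, s_max=0.132, n_steps=N_TEST)
        L = solve_forward(0.0, fig2_rates, params, settings)
        assert L[0] == 1e-8
        assert np.all(L > 0)

    def test_out_of_bounds_schedule_rejected(self, fig2_rates, fig2_params, settings):
        bad = np.full(N_TEST + 1, 0.2)  # > s_max = 0.132
        with pytest.raises(DomainError):
            solve_forward(bad, fig2_rates, fig2_params, settings)

    def test_callable_schedule(self, fig2_rates, fig2_params, settings):
        L_callable = solve_forward(lambda t: 0.1, fig2_rates, fig2_params, settings)
        L_scalar = solve_forward(0.1, fig2_rates, fig2_params, settings)
        np.testing.assert_allclose(L_callable, L_scalar, rtol=1e-14)


class TestEvaluateObjective:
    def test_zero_control_closed_form(self, fig2_rates, fig2_params, settings):
        t = np.linspace(0, 1, N_TEST + 1)
        L = solve_forward(0.0, fig2_rates, fig2_params, settings)
        phi = evaluate_objective(t, L, np.zeros_like(t), fig2_rates)
        a = 2.0001
        assert phi == pytest.approx((1 - math.exp(-a)) / a, rel=1e-7)

    def test_p_equals_s_gives_zero(self, settings):
        rates = const_rates(p=0.1)
        params = SeasonParams(s_max=0.5, n_steps=N_TEST)
        t = np.linspace(0, 1, N_TEST + 1)
        L = solve_forward(0.1, rates, params, settings)
        phi = evaluate_objective(t, L, np.full_like(t, 0.1), rates)
        assert phi == pytest.approx(0.0, abs=1e-14)

    def test_optimal_dominates_zero_control(self, fig2_traj, fig2_rates,
                                            fig2_params, settings):
        t = np.linspace(0, 1, N_TEST + 1)
        L0 = solve_forward(0.0, fig2_rates, fig2_params, settings)
        phi0 = evaluate_objective(t, L0, np.zeros_like(t), fig2_rates)
        assert fig2_traj.phi > phi0


class TestSolve:
    def test_trajectory_invariants(self, fig2_traj):
        fig2_traj.validate()
        assert fig2_traj.lam[-1] == 0.0
        assert np.all(fig2_traj.L > 0)
        assert np.all(np.diff(fig2_traj.L) <= 0)

    def test_smax_zero_matches_closed_form(self, fig2_rates, settings):
        params = SeasonParams(s_max=0.0, n_steps=N_TEST)
        traj = solve(fig2_rates, params, settings)
        a = 2.0001
        assert np.all(traj.s == 0.0)
        assert traj.phi == pytest.approx((1 - math.exp(-a)) / a, rel=1e-7)

    def test_L0_linearity(self, fig2_rates, fig2_params, settings):
        import dataclasses
        traj1 = solve(fig2_rates, fig2_params, settings)
        traj2 = solve(
            fig2_rates, dataclasses.replace(fig2_params, L0=2.0), settings
        )
        assert traj2.phi == pytest.approx(2.0 * traj1.phi, rel=1e-12)
        np.testing.assert_allclose(traj2.s, traj1.s, atol=1e-14)
        np.testing.assert_allclose(traj2.lam, traj1.lam, atol=1e-14)

    def test_hamiltonian_maximized_on_grid(self, fig2_traj, fig2_rates):
        idx = np.arange(0, N_TEST + 1, 50)
        s_grid = np.linspace(0.0, 0.132, 1001)
        for i in idx:
            H_all = hamiltonian(
                fig2_traj.L[i], fig2_traj.lam[i], fig2_traj.t[i], s_grid,
                fig2_rates,
            )
            H_hat = hamiltonian(
                fig2_traj.L[i], fig2_traj.lam[i], fig2_traj.t[i],
                fig2_traj.s[i], fig2_rates,
            )
            assert H_hat >= np.max(H_all) - 1e-10

    def test_lambda_nonnegative(self, fig2_traj, fig4_b4_traj):
        assert np.all(fig2_traj.lam >= -1e-14)
        assert np.all(fig4_b4_traj.lam >= -1e-14)

    def test_interior_first_order_condition(self, fig2_traj):
        s, lam = fig2_traj.s, fig2_traj.lam
        interior = (s > 1e-6) & (s < 0.132 * (1 - 1e-6))
        lhs = (1.0 + fig2_traj.b_vals[interior] * s[interior]) ** 2
        rhs = lam[interior] * fig2_traj.b_vals[interior] * fig2_traj.h_vals[interior]
        np.testing.assert_allclose(lhs, rhs, rtol=1e-10)

    def test_grid_refinement_convergence(self, fig2_rates, fig2_params):
        phi_coarse = solve(fig2_rates, fig2_params,
                           SolverSettings(n_steps=10_000)).phi
        phi_fine = solve(fig2_rates, fig2_params,
                         SolverSettings(n_steps=20_000)).phi
        assert abs(phi_fine - phi_coarse) < 1e-6 * abs(phi_fine)

    def test_adaptive_matches_fixed(self, fig2_rates, fig2_params):
        fixed = solve(fig2_rates, fig2_params, SolverSettings(n_steps=N_TEST))
        adaptive = solve(
            fig2_rates, fig2_params,
            SolverSettings(integrator="adaptive", n_steps=N_TEST,
                           rel_tol=1e-10, abs_tol=1e-12),
        )
        assert adaptive.phi == pytest.approx(fixed.phi, rel=1e-7)
        np.testing.assert_allclose(adaptive.lam, fixed.lam, atol=1e-7)

    def test_period_mismatch_rejected(self, fig2_params, settings):
        rates = RateSet(
            p=RateFunction.constant(1.0, period=2.0),
            h=RateFunction.constant(2.0, period=2.0),
            b_eff=RateFunction.constant(2.0, period=2.0),
        )
        with pytest.raises(DomainError):
            solve(rates, fig2_params, settings)
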