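"""Two-site ERK ODE model: rates, steady state, integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from erkensemble.erk_model import (
    ErkModelParams,
    erk_rhs,
    predicted_perk,
    simulate_erk,
    steady_state_init,
)
from erkensemble.exceptions import ValidationError
from erkensemble.mek_input import MekInputParams, eval_mek_input

TIMES = np.array([0.0, 5.0, 15.0, 30.0, 60.0, 120.0])

REF_PARAMS = ErkModelParams(
    kc1=1.2, kc2=1.5, K1=0.3, K2=0.3, Vp1=0.25, Vp2=0.2, P1=0.3, P2=0.3,
    phi=1.0, scale=1.0,
)
REF_INPUT = MekInputParams(0.06, 1.6, 3.0, 45.0)
ZERO_INPUT = MekInputParams(0.0, 0.0, 1.0, 1.0)


class TestRhs:
    def test_no_input_no_phospho_is_quiescent(self):
        d = erk_rhs(np.array([1.0, 0.0, 0.0]), 0.0, REF_PARAMS, ZERO_INPUT)
        np.testing.assert_array_equal(d, np.zeros(3))

    def test_hand_computed_unphosphorylation_balance(self):
        # dx0/dt = -kc1*u*x0/(K1+x0) + phi*Vp1*x1/(P1+x1)
        #        = -1*0.4*0.5/(0.5+0.5) + 2*0.2*0.3/(0.1+0.3) = -0.2+0.3 = 0.1
        params = ErkModelParams(
            kc1=1.0, kc2=1e-12, K1=0.5, K2=1.0, Vp1=0.2, Vp2=1e-12,
            P1=0.1, P2=1.0, phi=2.0,
        )
        const_u = MekInputParams(0.4, 0.0, 1.0, 1.0)
        d = erk_rhs(np.array([0.5, 0.3, 0.2]), 0.0, params, const_u)
        assert d[0] == pytest.approx(0.1, abs=1e-12)
        assert d.sum() == pytest.approx(0.0, abs=1e-15)

    @settings(max_examples=50, deadline=None)
    @given(
        x1=st.floats(0.0, 1.0),
        frac=st.floats(0.0, 1.0),
        u=st.floats(0.0, 2.0),
        phi=st.floats(0.0, 10.0),
    )
    def test_derivatives_always_sum_to_zero(self, x1, frac, u, phi):
        x2 = (1.0 - x1) * frac
        x0 = 1.0 - x1 - x2
        params = ErkModelParams(
            kc1=1.2, kc2=1.5, K1=0.3, K2=0.3, Vp1=0.25, Vp2=0.2,
            P1=0.3, P2=0.3, phi=phi,
        )
        d = erk_rhs(np.array([x0, x1, x2]), 0.0, params,
                    MekInputParams(u, 0.0, 1.0, 1.0))
        # dx1 is defined as -(dx0 + dx2); the total drifts only by rounding
        assert d.sum() == pytest.approx(0.0, abs=1e-15)

    def test_invalid_state_rejected(self):
        with pytest.raises(ValidationError):
            erk_rhs(np.array([0.8, 0.4, 0.2]), 0.0, REF_PARAMS, REF_INPUT)
        with pytest.raises(ValidationError):
            erk_rhs(np.array([1.2, -0.3, 0.1]), 0.0, REF_PARAMS, REF_INPUT)


class TestSteadyState:
    def test_zero_input_fixed_point_is_dephosphorylated(self):
        np.testing.assert_array_equal(
            steady_state_init(REF_PARAMS, 0.0), [1.0, 0.0, 0.0]
        )

    @pytest.mark.parametrize("basal", [0.05, 0.3, 1.0])
    def test_residual_below_tolerance(self, basal):
        state = steady_state_init(REF_PARAMS, basal)
        rhs = erk_rhs(state, 0.0, REF_PARAMS, MekInputParams(basal, 0.0, 1.0, 1.0))
        assert np.max(np.abs(rhs)) < 1e-10

    def test_agrees_with_long_time_integration(self):
        # independent oracle: relax the ODE under constant input for 1e5 min
        from scipy.integrate import solve_ivp

        basal = 0.4
        const_input = MekInputParams(basal, 0.0, 1.0, 1.0)

        def rhs(t, y):
            return erk_rhs(y, t, REF_PARAMS, const_input)

        sol = solve_ivp(
            rhs, (0.0, 1e5), [1.0, 0.0, 0.0], method="LSODA",
            rtol=1e-10, atol=1e-12,
        )
        state = steady_state_init(REF_PARAMS, basal)
        np.testing.assert_allclose(state, sol.y[:, -1], atol=1e-6)


class TestSimulate:
    def test_zero_input_trajectory_is_constant(self):
        traj = simulate_erk(REF_PARAMS, ZERO_INPUT, TIMES)
        np.testing.assert_array_equal(traj, np.tile([1.0, 0.0, 0.0], (6, 1)))

    def test_mass_conservation_along_trajectory(self):
        traj = simulate_erk(REF_PARAMS, REF_INPUT, TIMES)
        assert np.max(np.abs(traj.sum(axis=1) - 1.0)) < 1e-6
        assert np.all(traj >= -1e-9)

    def test_phosphatase_upregulation_suppresses_perk(self):
        lo = simulate_erk(REF_PARAMS.with_phi(1.0), REF_INPUT, TIMES)
        same = simulate_erk(REF_PARAMS.with_phi(1.0), REF_INPUT, TIMES)
        hi = simulate_erk(REF_PARAMS.with_phi(3.0), REF_INPUT, TIMES)
        np.testing.assert_array_equal(lo, same)
        assert np.all(hi[1:, 2] < lo[1:, 2])

    def test_monotone_in_phi_over_ladder(self):
        prev = None
        for phi in (1.0, 2.0, 4.0, 8.0):
            x2 = simulate_erk(REF_PARAMS.with_phi(phi), REF_INPUT, TIMES)[1:, 2]
            if prev is not None:
                assert np.all(x2 <= prev + 1e-9)
            prev = x2

    def test_monotone_in_input_amplitude(self):
        small = MekInputParams(0.06, 0.8, 3.0, 45.0)
        large = MekInputParams(0.06, 1.6, 3.0, 45.0)
        x2_small = simulate_erk(REF_PARAMS, small, TIMES)[:, 2]
        x2_large = simulate_erk(REF_PARAMS, large, TIMES)[:, 2]
        assert np.all(x2_large >= x2_small - 1e-9)

    def test_step_input_converges_to_new_fixed_point(self):
        # u steps from 0.05 to ~0.55 (decay time >> simulation span), so
        # the trajectory must relax to the fixed point of the new level
        step_input = MekInputParams(0.05, 0.5, 0.5, 1e9)
        u_late = eval_mek_input(step_input, 1e4)
        target = steady_state_init(REF_PARAMS, u_late)
        traj = simulate_erk(REF_PARAMS, step_input, np.array([0.0, 1e4]))
        np.testing.assert_allclose(traj[-1], target, atol=1e-6)

    def test_solver_independence_fixed_step_rk4(self):
        # classical RK4 at dt = 0.001 min as an independent integrator
        dt = 0.001
        n = int(TIMES[-1] / dt)
        y = steady_state_init(REF_PARAMS, eval_mek_input(REF_INPUT, 0.0))
        out = {0.0: y.copy()}
        targets = set(TIMES.tolist())

        def f(t, y):
            from erkensemble.erk_model import _rhs_raw

            return _rhs_raw(y[0], y[1], y[2], eval_mek_input(REF_INPUT, t),
                            REF_PARAMS)

        t = 0.0
        for i in range(n):
            k1 = f(t, y)
            k2 = f(t + dt / 2, y + dt / 2 * k1)
            k3 = f(t + dt / 2, y + dt / 2 * k2)
            k4 = f(t + dt, y + dt * k3)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t = (i + 1) * dt
            if round(t, 6) in targets:
                out[round(t, 6)] = y.copy()
        ref = np.array([out[t] for t in TIMES])
        adaptive = simulate_erk(REF_PARAMS, REF_INPUT, TIMES)
        np.testing.assert_allclose(adaptive, ref, atol=1e-5)

    def test_times_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            simulate_erk(REF_PARAMS, REF_INPUT, np.array([5.0, 15.0]))
        with pytest.raises(ValueError):
            simulate_erk(REF_PARAMS, REF_INPUT, np.array([0.0, 10.0, 10.0]))


class TestPredictedPerk:
    def test_scale_is_linear(self):
        base = predicted_perk(REF_PARAMS, REF_INPUT, TIMES)
        doubled = predicted_perk(
            ErkModelParams(**{**REF_PARAMS.__dict__, "scale": 2.0}),
            REF_INPUT, TIMES,
        )
        np.testing.assert_allclose(doubled, 2.0 * base, rtol=1e-9)
        unit = predicted_perk(REF_PARAMS, REF_INPUT, TIMES)
        traj = simulate_erk(REF_PARAMS, REF_INPUT, TIMES)
        np.testing.assert_array_equal(unit, traj[:, 2] * REF_PARAMS.scale)

    def test_zero_input_prediction_is_zero(self):
        np.testing.assert_array_equal(
            predicted_perk(REF_PARAMS, ZERO_INPUT, TIMES), np.zeros(6)
        )


class TestFastPathAgreement:
    def test_compiled_integrator_matches_scipy(self):
        """The compiled sampler path and the scipy reference agree."""
        from erkensemble._fastsim import fast_x2_trajectory

        for phi in (1.0, 3.61):
            p = REF_PARAMS.with_phi(phi)
            ref = simulate_erk(p, REF_INPUT, TIMES)[:, 2]
            fast = fast_x2_trajectory(p.as_array(), phi, REF_INPUT.as_array(), TIMES)
            np.testing.assert_allclose(fast, ref, atol=1e-6)
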