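"""Myofilament model: troponin, regulatory switching, crossbridges, twitch."""

import math
from dataclasses import replace

import numpy as np
import pytest
from scipy.linalg import expm

from cardioemd import MechParameters, run_twitch
from cardioemd.ionic_model import EPTrace
from cardioemd.myofilament_model import (
    MechDivergenceError,
    MechState,
    crossbridge_rates,
    distortion_update,
    duty_fractions,
    initial_mech_state,
    regulatory_rates,
    single_overlap,
    step_sl,
    total_force,
    troponin_update,
    xb_cycle_update,
)

P = MechParameters()


def _rest_state(**overrides):
    st = initial_mech_state(7e-5, P)
    for key, val in overrides.items():
        setattr(st, key, val)
    return st


def _flat_trace(cai_level, bcl=300.0):
    n = int(bcl)
    return EPTrace(dt=1.0, v=np.full(n, -85.0), cai=np.full(n, cai_level),
                   bcl=bcl)


class TestTroponin:
    def test_zero_calcium_zero_occupancy_is_absorbing(self):
        h, l = troponin_update(0.0, 0.0, 0.0, P, 0.01)
        assert h == 0.0 and l == 0.0

    def test_steady_state_closed_form(self):
        cai = 5e-4
        h, l = 0.0, 0.0
        for _ in range(100000):
            h, l = troponin_update(h, l, cai, P, 0.01)
        kon = P.k_on
        assert h == pytest.approx(kon * cai / (kon * cai + P.k_off_h), rel=1e-6)
        assert l == pytest.approx(kon * cai / (kon * cai + P.k_off_l), rel=1e-6)

    def test_step_matches_exact_linear_solution(self):
        cai, dt = 1e-3, 0.001
        rate = P.k_on * cai + P.k_off_h
        h = 0.2
        n = 5000
        for _ in range(n):
            h, _ = troponin_update(h, 0.0, cai, P, dt)
        h_inf = P.k_on * cai / rate
        exact = h_inf + (0.2 - h_inf) * math.exp(-rate * n * dt)
        assert h == pytest.approx(exact, rel=1e-4)


class TestRegulatoryRates:
    def test_half_activation_gives_sqrt_half(self):
        # force Trop_Regulatory = perm50 by equal saturations
        kn, kp = regulatory_rates(P.sl_0, P.perm50, P.perm50, P)
        permtot = math.sqrt(0.5)
        assert kn == pytest.approx(P.k_n_p * permtot, rel=1e-12)
        assert kp == pytest.approx(P.k_p_n / permtot, rel=1e-12)

    def test_inverse_cap_engages_at_zero_activation(self):
        kn, kp = regulatory_rates(P.sl_0, 0.0, 0.0, P)
        assert kn == 0.0
        assert kp == P.k_p_n * 100.0  # cap exactly

    def test_temperature_factors_vanish_at_37(self):
        warm = replace(P, tmpc=37.0)
        cold = replace(P, tmpc=27.0)
        kn37, _ = regulatory_rates(P.sl_0, 0.6, 0.6, warm)
        kn27, _ = regulatory_rates(P.sl_0, 0.6, 0.6, cold)
        assert kn27 == pytest.approx(kn37 / warm.q_kn_p, rel=1e-12)
        # at 37 the rate is exactly the base rate times permtot
        sovf_thin, _ = single_overlap(P.sl_0, warm)
        trop_reg = 0.6
        permtot = math.sqrt(1 / (1 + (P.perm50 / trop_reg) ** P.n_perm))
        assert kn37 == pytest.approx(P.k_n_p * permtot, rel=1e-12)


class TestCrossbridgeCycle:
    def test_all_rates_zero_is_a_fixed_point(self):
        st = _rest_state(n_xb=0.4, p_xb=0.3, xb_prer=0.2, xb_postr=0.1)
        out = xb_cycle_update(st, 0, 0, 0, 0, 0, 0, 0, 0.01)
        assert out.as_array() == pytest.approx(st.as_array())

    def test_occupancy_sums_conserved_each_step(self):
        st = _rest_state(n_xb=0.4, p_xb=0.3, xb_prer=0.2, xb_postr=0.1,
                         n_noxb=0.7, p_noxb=0.3)
        rates = crossbridge_rates(P.sl_0, 0.0, P.x_0, P)
        out = xb_cycle_update(st, 0.3, 0.1, *rates, 0.005)
        assert (out.n_xb + out.p_xb + out.xb_prer + out.xb_postr
                == pytest.approx(1.0, abs=1e-12))
        assert out.n_noxb + out.p_noxb == pytest.approx(1.0, abs=1e-12)

    def test_optimal_condition_approaches_duty_fractions(self):
        """With N→P switching much faster than P→N, the strongly bound
        occupancies converge to the closed-form duty fractions."""
        fappt, gappt, hft, hbt, gxbt = (P.f_app, P.g_app, P.h_f, P.h_b, P.g_xb)
        st = _rest_state()
        st.n_xb, st.p_xb, st.xb_prer, st.xb_postr = 1.0, 0.0, 0.0, 0.0
        for _ in range(200000):
            st = xb_cycle_update(st, 5.0, 1e-6, fappt, gappt, hft, hbt, gxbt,
                                 0.005)
        prer, postr = duty_fractions(fappt, gappt, hft, hbt, gxbt)
        assert st.xb_prer == pytest.approx(prer, rel=1e-3)
        assert st.xb_postr == pytest.approx(postr, rel=1e-3)

    def test_one_step_matches_matrix_exponential(self):
        """An Euler step of the linear 4-state system agrees with the
        matrix-exponential propagator to first order in dt."""
        kn, kp = 0.2, 0.05
        fappt, gappt, hft, hbt, gxbt = 0.5, 0.07, 2.0, 0.4, 0.07
        a = np.array([
            [-kn, kp, 0.0, 0.0],
            [kn, -(kp + fappt), gappt, gxbt],
            [0.0, fappt, -(gappt + hft), hbt],
            [0.0, 0.0, hft, -(hbt + gxbt)],
        ])
        x0 = np.array([0.4, 0.3, 0.2, 0.1])
        dt = 1e-4
        exact = expm(a * dt) @ x0
        st = _rest_state(n_xb=0.4, p_xb=0.3, xb_prer=0.2, xb_postr=0.1)
        out = xb_cycle_update(st, kn, kp, fappt, gappt, hft, hbt, gxbt, dt)
        got = np.array([out.n_xb, out.p_xb, out.xb_prer, out.xb_postr])
        np.testing.assert_allclose(got, exact, atol=5 * dt**2)

    def test_negative_occupancy_rejected(self):
        st = _rest_state(p_xb=-1e-6)
        with pytest.raises(MechDivergenceError):
            st.validate()


class TestDistortion:
    RATES = (P.f_app, P.g_app, P.h_f, P.h_b, P.g_xb)

    def test_isometric_strains_are_a_fixed_point(self):
        xp, xq = distortion_update(0.0, P.x_0, 0.0, 0.1, 0.1, *self.RATES,
                                   P, 0.01)
        assert xp == pytest.approx(0.0, abs=1e-15)
        assert xq == pytest.approx(P.x_0, rel=1e-12)

    def test_pure_advection_when_rates_vanish(self):
        dsl = -0.4
        dt = 0.01
        xp, xq = distortion_update(0.0, P.x_0, dsl, 0.1, 0.1, 0, 0, 0, 0, 0,
                                   P, dt)
        assert xp == pytest.approx(0.5 * dsl * dt)
        assert xq == pytest.approx(P.x_0 + 0.5 * dsl * dt)

    def test_step_matches_reference_integration(self):
        from scipy.integrate import solve_ivp
        fappt, gappt, hft, hbt, gxbt = self.RATES
        prer, postr = duty_fractions(*self.RATES)
        x0 = P.x_0

        def rhs(t, x):
            return [
                (P.phi / prer) * (fappt * (-x[0]) + hbt * (x[1] - x0 - x[0])),
                (P.phi / postr) * hft * (x[0] + x0 - x[1]),
            ]

        start = (0.002, 0.004)
        ref = solve_ivp(rhs, (0, 0.05), start, rtol=1e-10, atol=1e-13)
        xp, xq = start
        for _ in range(500):
            xp, xq = distortion_update(xp, xq, 0.0, 0.1, 0.1, *self.RATES,
                                       P, 0.0001)
        assert xp == pytest.approx(ref.y[0, -1], rel=2e-3)
        assert xq == pytest.approx(ref.y[1, -1], rel=2e-3)


class TestForceAndLength:
    def test_no_strong_binding_no_active_force(self):
        st = _rest_state(xb_prer=0.0, xb_postr=0.0)
        f_active, _, _, _ = total_force(st, P)
        assert f_active == 0.0

    def test_initial_length_force_identity(self):
        # at SL = SL_0 the afterload (series mode) and net passive terms
        # cancel, so the integrand is exactly −F_active
        p_se = replace(P, contraction_mode="series_elastic")
        st = _rest_state(xb_prer=0.05, xb_postr=0.05, x_prer=0.001,
                         x_postr=P.x_0)
        f_active, f_passive, f_after, f_total = total_force(st, p_se)
        assert f_after == 0.0
        assert f_total == pytest.approx(-f_active, rel=1e-12)

    def test_active_force_formula_hand_evaluated(self):
        st = _rest_state(xb_prer=0.1, xb_postr=0.2, x_prer=0.002,
                         x_postr=0.008)
        _, sovf_thick = single_overlap(st.sl, P)
        _, postr_max = duty_fractions(P.f_app, P.g_app, P.h_f, P.h_b, P.g_xb)
        expected = sovf_thick * (0.002 * 0.1 + 0.008 * 0.2) / (P.x_0 * postr_max)
        f_active, _, _, _ = total_force(st, P)
        assert f_active == pytest.approx(expected, rel=1e-12)

    def test_step_sl_rest_is_stationary(self):
        p_se = replace(P, contraction_mode="series_elastic")
        st = initial_mech_state(0.0, p_se)
        out = step_sl(st, p_se, 0.001)
        assert out.sl == pytest.approx(st.sl, abs=1e-12)

    def test_constant_negative_integral_shortens_monotonically(self):
        p_se = replace(P, contraction_mode="series_elastic")
        st = initial_mech_state(0.0, p_se)
        st.integral_force = -2e-5
        last = st.sl
        for _ in range(200):
            st = step_sl(st, p_se, 0.001)
            st.integral_force = -2e-5   # hold the force integral fixed
            assert st.sl <= last + 1e-15
            last = st.sl
        assert st.sl < p_se.sl_0

    def test_divergence_guard(self):
        st = _rest_state()
        st.integral_force = -10.0
        with pytest.raises(MechDivergenceError):
            for _ in range(10000):
                st = step_sl(st, P, 0.01)
                st.integral_force = -10.0


class TestTwitch:
    def test_resting_calcium_produces_no_shortening(self):
        mech = run_twitch(_flat_trace(7e-5), P)
        assert np.all(mech.length_norm > 0.999)
        assert mech.length_norm[0] == pytest.approx(1.0, abs=1e-12)

    def test_zero_calcium_nullity(self):
        mech = run_twitch(_flat_trace(0.0), P)
        assert mech.tension_norm.max() < 1e-6
        assert mech.length_norm.min() > 0.999

    def test_tension_scale_only_rescales_kpa(self, normal_traces):
        tr = normal_traces[600.0]
        a = run_twitch(tr, P)
        b = run_twitch(tr, replace(P, t_max_kpa=2 * P.t_max_kpa,
                                   afterload_kpa=2 * P.afterload_kpa))
        np.testing.assert_array_equal(a.tension_norm, b.tension_norm)
        np.testing.assert_array_equal(a.length_norm, b.length_norm)
        np.testing.assert_allclose(b.tension_kpa, 2 * a.tension_kpa)

    def test_normal_beat_contracts(self, normal_twitch_600):
        assert normal_twitch_600.length_norm.min() <= 0.99
        assert normal_twitch_600.tension_kpa.max() >= 20.0

    def test_monotone_activation(self, normal_traces):
        tr = normal_traces[600.0]
        peaks = []
        for c in (0.5, 1.0, 2.0):
            scaled = EPTrace(dt=tr.dt, v=tr.v, cai=tr.cai * c, bcl=tr.bcl)
            peaks.append(run_twitch(scaled, P).tension_norm.max())
        assert peaks[0] <= peaks[1] <= peaks[2]

    def test_occupancy_conservation_over_full_twitch(self, normal_traces):
        _, final = run_twitch(normal_traces[600.0], P,
                              return_final_state=True)
        assert (final.n_noxb + final.p_noxb
                == pytest.approx(1.0, abs=1e-8))
        assert (final.n_xb + final.p_xb + final.xb_prer + final.xb_postr
                == pytest.approx(1.0, abs=1e-8))

    def test_determinism_bitwise(self, normal_traces):
        a = run_twitch(normal_traces[600.0], P)
        b = run_twitch(normal_traces[600.0], P)
        np.testing.assert_array_equal(a.tension_norm, b.tension_norm)
        np.testing.assert_array_equal(a.length_norm, b.length_norm)

    def test_step_halving_convergence(self, normal_traces):
        tr = normal_traces[600.0]
        a = run_twitch(tr, P)
        b = run_twitch(tr, replace(P, dt=P.dt / 2))
        assert a.tension_norm.max() == pytest.approx(b.tension_norm.max(),
                                                     rel=1e-3)
        assert a.length_norm.min() == pytest.approx(b.length_norm.min(),
                                                    abs=1e-4)
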