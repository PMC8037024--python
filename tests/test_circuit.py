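"""Core EMT switch, LOXL2 feedback wiring, steady states and stability."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.integrate import solve_ivp

from emtecm.circuit import (
    CircuitParams,
    MirnaSilencing,
    classify_state,
    find_steady_states,
    iecm,
    jacobian,
    mirna_modulation,
    rhs,
    shifted_hill,
)


class TestShiftedHill:
    def test_no_regulator(self):
        assert shifted_hill(0.0, 100.0, 2, 0.1) == 1.0

    def test_half_point_full_repression(self):
        assert shifted_hill(100.0, 100.0, 4, 0.0) == pytest.approx(0.5)

    def test_saturation(self):
        assert shifted_hill(1e12, 100.0, 2, 0.1) == pytest.approx(0.1, rel=1e-6)
        assert shifted_hill(1e12, 100.0, 2, 7.5) == pytest.approx(7.5, rel=1e-6)


class TestMirnaModulation:
    def test_no_mirna(self):
        sil = MirnaSilencing(u0=1e4, l=(1, 0.6, 0.3), gm=(0, 0.04, 0.2),
                             gu=(0, 0.005, 0.05))
        L, Ym, Yu = mirna_modulation(0.0, sil)
        assert (L, Ym, Yu) == (1.0, 0.0, 0.0)

    def test_binomial_occupancies_normalized(self):
        from math import comb
        sil = MirnaSilencing(u0=1e4, l=(1.0,) * 7, gm=(1.0,) * 7, gu=(0.0,) * 7)
        for u in [0.0, 5e3, 1e4, 1e5]:
            # with all gm weights 1, Ym equals the sum of occupancies
            _L, Ym, _Yu = mirna_modulation(u, sil)
            assert Ym == pytest.approx(1.0)

    def test_single_site_half_occupancy(self):
        """n=1 at u=u0: M1 = 1/2 so L = 1 - (1 - l1)/2."""
        sil = MirnaSilencing(u0=1e4, l=(1.0, 0.4), gm=(0.0, 1.0), gu=(0.0, 1.0))
        L, Ym, Yu = mirna_modulation(1e4, sil)
        assert L == pytest.approx(1.0 - (1.0 - 0.4) / 2)
        assert Ym == pytest.approx(0.5)
        assert Yu == pytest.approx(0.5)

    def test_translation_monotone_decreasing(self):
        sil = MirnaSilencing(u0=1e4, l=(1, 0.6, 0.3), gm=(0, 0.04, 0.2),
                             gu=(0, 0.005, 0.05))
        u = np.linspace(0, 1e5, 200)
        L = np.array([mirna_modulation(v, sil)[0] for v in u])
        assert np.all(np.diff(L) < 0)


class TestIecm:
    def test_half_point(self, coupled_params):
        p = coupled_params
        assert iecm(p.K_LE, p) == pytest.approx(p.g_ECM / 2)

    def test_zero_concentration(self, coupled_params):
        assert iecm(0.0, coupled_params) == 0.0

    def test_zero_threshold_always_max(self, coupled_params):
        p = replace(coupled_params, K_LE=0.0)
        assert iecm(1e-9, p) == p.g_ECM
        assert iecm(1e9, p) == p.g_ECM

    def test_depends_only_on_ratio(self, coupled_params):
        p1 = replace(coupled_params, K_LE=5e4)
        p2 = replace(coupled_params, K_LE=1e5)
        assert iecm(2.0e4, p1) == pytest.approx(iecm(4.0e4, p2), rel=1e-12)


class TestRhs:
    def test_loxl2_steady_state_half_activation(self, coupled_params):
        """At Z = KZL the LOXL2 steady level is gLOXL/(2 kLOXL)."""
        p = coupled_params
        c_star = p.g_LOXL / (2 * p.k_LOXL)
        x = np.array([0, 0, p.K_ZL, 0, 0, 0, c_star])
        assert rhs(x, p, 0.0)[6] == pytest.approx(0.0, abs=1e-9)

    def test_loxl2_saturation(self, coupled_params):
        p = coupled_params
        c_star = p.g_LOXL / p.k_LOXL
        x = np.array([0, 0, 1e15, 0, 0, 0, c_star])
        assert rhs(x, p, 0.0)[6] == pytest.approx(0.0, abs=1e-6 * c_star)

    def test_loxl2_steady_state_monotone_in_zeb(self, coupled_params):
        p = coupled_params
        zs = np.linspace(1e3, 1e6, 50)
        c = p.g_LOXL / (p.k_LOXL * (1 + p.K_ZL / zs))
        assert np.all(np.diff(c) > 0)

    def test_severed_feedback_matches_baseline_core(self, coupled_params):
        """With gECM=0 the core dynamics ignore LOXL2 entirely."""
        p0 = coupled_params.baseline()
        x = np.array([5e3, 800.0, 4e5, 2e3, 300.0, 2e5, 0.0])
        xc = x.copy()
        xc[6] = 7.7e4
        f_a = rhs(x, p0, 50_000.0)[:6]
        f_b = rhs(xc, p0, 50_000.0)[:6]
        np.testing.assert_allclose(f_a, f_b, rtol=1e-14)

    def test_negative_state_rejected(self, baseline_params):
        with pytest.raises(ValueError):
            rhs(np.array([-1.0, 0, 0, 0, 0, 0, 0]), baseline_params, 0.0)

    def test_trajectories_stay_nonnegative(self, baseline_params):
        """Non-negativity is preserved from non-negative initial states."""
        for I in (0.0, 60_000.0):
            sol = solve_ivp(
                lambda t, x: rhs(np.maximum(x, 0.0), baseline_params, I),
                (0, 500.0), np.array([1e3, 10.0, 1e3, 1e3, 10.0, 1e3, 0.0]),
                method="LSODA", rtol=1e-8, atol=1e-6,
            )
            assert sol.success
            assert sol.y.min() > -1e-3


class TestSteadyStates:
    def test_monostable_epithelial_at_low_signal(self, baseline_params):
        states = find_steady_states(baseline_params, 10_000.0)
        assert len(states) == 1
        st, stable = states[0]
        assert stable
        assert classify_state(st, baseline_params) == "epithelial"

    def test_tristable_window(self, baseline_params):
        """Three stable states with interleaved unstable ones mid-window."""
        states = find_steady_states(baseline_params, 55_000.0)
        stables = [s for s, ok in states if ok]
        unstables = [s for s, ok in states if not ok]
        assert len(stables) == 3
        assert len(unstables) == 2
        z = sorted(s.Z for s in stables)
        assert z[0] < 2e4 < z[1] < 2e5 < z[2]

    def test_every_root_satisfies_rhs(self, baseline_params):
        for I in (30_000.0, 55_000.0, 90_000.0):
            for st, _ in find_steady_states(baseline_params, I):
                f = rhs(st.to_array(), baseline_params, I)
                scale = np.maximum(np.abs(st.to_array()), 1.0)
                assert np.max(np.abs(f) / scale) < 1e-6

    def test_integration_converges_to_found_roots(self, baseline_params):
        """Long-time integration from near each stable root stays on it."""
        I = 55_000.0
        for st, stable in find_steady_states(baseline_params, I):
            if not stable:
                continue
            x0 = st.to_array() * 1.01
            sol = solve_ivp(
                lambda t, x: rhs(np.maximum(x, 0.0), baseline_params, I),
                (0, 2000.0), x0, method="LSODA", rtol=1e-10, atol=1e-8,
            )
            xf = sol.y[:, -1]
            scale = np.maximum(np.abs(st.to_array()), 1.0)
            assert np.max(np.abs(xf - st.to_array()) / scale) < 1e-3

    def test_jacobian_matches_directional_derivative(self, baseline_params, rng):
        x = np.array([5e3, 800.0, 4e5, 2e3, 300.0, 2e5, 5e4])
        J = jacobian(x, baseline_params, 50_000.0)
        v = rng.standard_normal(7)
        h = 1e-4
        num = (rhs(x + h * v * np.maximum(x, 1), baseline_params, 50_000.0)
               - rhs(x - h * v * np.maximum(x, 1), baseline_params, 50_000.0)) / (2 * h)
        np.testing.assert_allclose(num, J @ (v * np.maximum(x, 1)),
                                   rtol=1e-3, atol=1e-3)


class TestHysteresis:
    def test_mesenchymal_locked_at_zero_signal(self, coupled_params):
        """Strong feedback keeps a stable mesenchymal root at I = 0 where
        the baseline supports only the epithelial state."""
        strong = replace(coupled_params, K_LE=2e4)
        full = find_steady_states(strong, 0.0)
        base = find_steady_states(coupled_params.baseline(), 0.0)
        m_full = [s for s, ok in full
                  if ok and classify_state(s, strong) == "mesenchymal"]
        m_base = [s for s, ok in base
                  if ok and classify_state(s, coupled_params) == "mesenchymal"]
        assert len(m_full) >= 1
        assert len(m_base) == 0
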