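import math
from dataclasses import replace

import numpy as np
import pytest

from proteodyn.errors import ParameterError
from proteodyn.phase_reduction import (
    SelfCoupledParams,
    kappa_sweep,
    period_analytic,
    period_numeric,
    phase_rhs,
)

BASE_PARAMS = SelfCoupledParams()  # omega = a = b = c = lam = 1, kappa = 0, tau = 0


class TestPhaseRhs:
    def test_coupling_vanishes_at_zero_phase(self):
        p = replace(BASE_PARAMS, kappa=0.7, tau=1.0)
        assert phase_rhs(0.0, 0.5, p) == p.omega

    def test_zero_coupling_is_free_rotation(self):
        for th in (0.1, 1.0, 2.5):
            assert phase_rhs(th, th - 0.3, BASE_PARAMS) == BASE_PARAMS.omega

    def test_direct_substitution(self):
        p = replace(BASE_PARAMS, kappa=0.4)
        expected = p.omega - 0.4 * math.tanh(1.0)
        assert phase_rhs(math.pi / 2, 0.0, p) == pytest.approx(expected)


class TestPeriodNumeric:
    @pytest.mark.parametrize("system", ["full", "phase"])
    def test_uncoupled_period_is_two_pi(self, system):
        res = period_numeric(system, BASE_PARAMS)
        assert res.period == pytest.approx(2 * math.pi, abs=1e-7)

    def test_uncoupled_scales_with_omega(self):
        p = replace(BASE_PARAMS, omega=2.5)
        assert period_numeric("full", p).period == pytest.approx(2 * math.pi / 2.5, abs=1e-7)

    def test_invalid_system_rejected(self):
        with pytest.raises(ParameterError):
            period_numeric("nope", BASE_PARAMS)


class TestPeriodAnalytic:
    @pytest.mark.parametrize("form", ["order2", "small_tau", "leading", "leading_consistent"])
    def test_expansions_collapse_at_zero_coupling(self, form):
        p = replace(BASE_PARAMS, omega=1.7, tau=0.4)
        assert period_analytic(p, form).period == pytest.approx(2 * math.pi / 1.7)

    def test_order2_frozen_value(self):
        """At omega=a=b=c=lam=1, tau=0, kappa=0.1 the expansion is 2*pi + pi/600."""
        p = replace(BASE_PARAMS, kappa=0.1)
        assert period_analytic(p, "order2").period == pytest.approx(
            2 * math.pi + math.pi / 600, abs=1e-12
        )

    def test_order2_matches_symbolic_rederivation(self):
        """Independent sympy derivation of the small-c period expansion.

        Expand T = (1/om)(2*pi - kappa I1/om + kappa^2 I2/om^2) with
        I1 = int f, I2 = int f^2 over one cycle, f built from the cubic
        tanh truncation and the free-running delayed phase, keeping terms
        through c^4.
        """
        import sympy as sp

        th, om_s, tau_s, a_s, c_s, lam_s = sp.symbols(
            "theta omega tau a c lambda", positive=True
        )
        asl = a_s * sp.sqrt(lam_s)
        g = c_s * asl * sp.cos(th - om_s * tau_s)
        f = -sp.sin(th) / asl * (g - g**3 / 3)
        i1 = sp.integrate(f, (th, 0, 2 * sp.pi))
        i2_full = sp.expand(sp.integrate(sp.expand_trig(sp.expand(f**2)), (th, 0, 2 * sp.pi)))
        i2 = sum(t for t in sp.Add.make_args(i2_full) if sp.degree(t, c_s) <= 4)

        subs = {om_s: 1.3, a_s: 0.8, c_s: 0.7, lam_s: 1.2, tau_s: 0.9}
        for kappa in (0.05, 0.2):
            t_sym = (
                2 * sp.pi / om_s
                - sp.Rational(1) * kappa * i1 / om_s**2
                + kappa**2 * i2 / om_s**3
            )
            expected = float(t_sym.subs(subs))
            p = SelfCoupledParams(omega=1.3, a=0.8, b=1.0, c=0.7, lam=1.2, kappa=kappa, tau=0.9)
            assert period_analytic(p, "order2").period == pytest.approx(expected, abs=1e-12)

    def test_leading_forms_differ_by_factor_four(self):
        p = replace(BASE_PARAMS, kappa=0.1, tau=1.0)
        base = 2 * math.pi
        printed = period_analytic(p, "leading").period - base
        consistent = period_analytic(p, "leading_consistent").period - base
        assert consistent == pytest.approx(4 * printed)


class TestConsistencyOfRoutes:
    def test_analytic_error_matches_quadrature_oracle(self):
        """|T_order2 - T_phase| ~ Dc2 * kappa^2 with Dc2 from direct quadrature.

        At c = 1 the cubic tanh truncation leaves a genuine kappa^2-order
        discrepancy Dc2 = int sin^2(th) tanh^2(cos(th)) dth - pi/6; the
        measured gap must reproduce it (tau = 0).
        """
        from scipy.integrate import quad

        i_exact = quad(lambda x: np.sin(x) ** 2 * np.tanh(np.cos(x)) ** 2, 0, 2 * np.pi)[0]
        dc2 = i_exact - np.pi / 6
        for kappa in (0.05, 0.1):
            p = replace(BASE_PARAMS, kappa=kappa)
            gap = abs(
                period_analytic(p, "order2").period
                - period_numeric("phase", p).period
            )
            assert gap == pytest.approx(dc2 * kappa**2, rel=0.05)

    def test_phase_tracks_full_system(self):
        for tau in (0.0, 1.0):
            p = replace(BASE_PARAMS, kappa=0.05, tau=tau)
            t_full = period_numeric("full", p).period
            t_phase = period_numeric("phase", p).period
            assert t_phase == pytest.approx(t_full, abs=5e-3)


class TestKappaSweep:
    def test_zero_grid_collapses_to_base_period(self):
        table = kappa_sweep(BASE_PARAMS, [0.0], [0.0, 1.0])
        for col in ("T_full", "T_phase", "T_analytic_order2", "T_analytic_leading"):
            assert np.allclose(table[col], 2 * math.pi, atol=1e-7)

    def test_slope_sign_follows_sin_omega_tau(self):
        table = kappa_sweep(BASE_PARAMS, [0.05], [1.5, 4.5])
        base = 2 * math.pi
        by_tau = table.set_index("tau")
        assert by_tau.loc[1.5, "T_full"] > base    # sin(1.5) > 0 -> slowing
        assert by_tau.loc[4.5, "T_full"] < base    # sin(4.5) < 0 -> acceleration

    def test_slowing_as_excitation_decreases(self):
        periods = [
            period_numeric("full", replace(BASE_PARAMS, a=a, kappa=0.2)).period
            for a in (1.5, 1.0, 0.5)
        ]
        assert periods[0] < periods[1] < periods[2]
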