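import numpy as np
import pytest
from scipy.integrate import solve_ivp

import proteodyn as P
from proteodyn.errors import ConfigurationError, ParameterError
from proteodyn.proteopathy import SeedConfig


class TestInitializeState:
    def test_seed_mass_split(self, small_connectome):
        s = P.initialize_state(small_connectome)
        np.testing.assert_allclose(s.ut[s.ut > 0], 1e-2 / 12)
        np.testing.assert_allclose(s.vt[s.vt > 0], 5e-3)
        assert s.ut.sum() == pytest.approx(1e-2)
        assert s.vt.sum() == pytest.approx(1e-2)
        assert np.all(s.u == 1.0) and np.all(s.a == 1.0)

    def test_unknown_region_is_configuration_error(self, small_connectome):
        with pytest.raises(ConfigurationError):
            P.initialize_state(
                small_connectome, SeedConfig(amyloid_regions=("no such region",))
            )

    def test_empty_seed_lists_give_zero_toxic_derivatives(self, small_connectome):
        s = P.initialize_state(small_connectome, SeedConfig(amyloid_regions=(), tau_regions=()))
        ds = P.proteopathy_rhs(s, P.SpreadingParams(), P.DamageParams())
        assert np.all(ds.ut == 0) and np.all(ds.vt == 0)
        # Table defaults put the healthy pools at equilibrium u* = k0/k1 = 1
        assert np.abs(ds.u).max() < 1e-14 and np.abs(ds.v).max() < 1e-14


class TestRhs:
    def test_full_damage_edge_decay_rate(self, small_connectome):
        dp = P.DamageParams()
        s = P.initialize_state(small_connectome)
        s.qt[:] = 1.0
        ds = P.proteopathy_rhs(s, P.SpreadingParams(), dp)
        i, j = small_connectome.edge_i[0], small_connectome.edge_j[0]
        assert ds.w[i, j] == pytest.approx(-2 * dp.gamma)

    def test_a_derivative_vanishes_at_a_min(self, small_connectome):
        dp = P.DamageParams()
        s = P.initialize_state(small_connectome)
        s.qb[:] = 0.7
        s.qt[:] = 0.3
        s.a[:] = dp.a_min
        ds = P.proteopathy_rhs(s, P.SpreadingParams(), dp)
        assert np.abs(ds.a).max() == 0.0


class TestIntegration:
    def test_toxic_free_state_is_stationary(self, small_connectome):
        s0 = P.initialize_state(small_connectome, SeedConfig(amyloid_regions=(), tau_regions=()))
        series = P.integrate_proteopathy(s0, P.SpreadingParams(), P.DamageParams(), 30, 3)
        assert np.abs(series.field_array("u_toxic")).max() <= 1e-12
        assert np.abs(series.field_array("v_toxic")).max() <= 1e-12
        assert np.abs(series.field_array("u") - 1).max() <= 1e-9
        assert np.abs(series.field_array("a") - 1).max() <= 1e-12

    def test_snapshot_count_and_invariants(self, default_series):
        series = default_series
        dp = P.DamageParams()
        assert series.times.size == 11
        for name in ("q_beta", "q_tau"):
            q = series.field_array(name)
            assert np.all(q >= 0) and np.all(q <= 1)
            assert np.all(np.diff(q.mean(axis=1)) >= -1e-12)  # monotone damage
        a = series.field_array("a")
        assert np.all(a >= dp.a_min) and np.all(a <= dp.a_max)
        b = series.field_array("b")
        assert np.all(b >= dp.b_min) and np.all(b <= 1.0)
        assert np.all(np.diff(b, axis=0) <= 1e-12)  # b monotone nonincreasing
        for s in series.states:
            assert np.array_equal(s.w, s.w.T)
            assert np.all(s.w >= 0)
        # edge weights nonincreasing over time
        w_seq = np.stack([s.w[series.edge_i, series.edge_j] for s in series.states])
        assert np.all(np.diff(w_seq, axis=0) <= 1e-9)

    def test_biphasic_global_excitation(self, default_series):
        a_mean = default_series.field_array("a").mean(axis=1)
        assert a_mean.max() > 1.0  # early hyperexcitability
        assert a_mean[-1] < 1.0    # late collapse below baseline

    def test_refining_tolerances_is_consistent(self, small_connectome):
        s0 = P.initialize_state(small_connectome)
        coarse = P.integrate_proteopathy(s0.copy(), P.SpreadingParams(), P.DamageParams(), 30, 3)
        fine = P.integrate_proteopathy(
            s0.copy(), P.SpreadingParams(), P.DamageParams(), 30, 3,
            rtol=5e-9, atol=5e-12,
        )
        for name in ("u", "u_toxic", "v", "v_toxic", "q_beta", "q_tau", "a", "b"):
            diff = np.abs(coarse.field_array(name) - fine.field_array(name)).max()
            assert diff < 1e-6

    def test_probe_interval_must_divide_horizon(self, small_connectome):
        with pytest.raises(ParameterError):
            P.integrate_proteopathy(
                P.initialize_state(small_connectome),
                P.SpreadingParams(), P.DamageParams(), 30, 7,
            )


class TestCriticalRatio:
    def test_table_defaults(self):
        rep = P.critical_ratio(P.DamageParams(), 0.5, 0.2)
        assert rep.R_crit == pytest.approx(1.9 * 0.8 / 1.8)
        assert rep.a1_star == pytest.approx(0.05)

    def test_unit_damages_interior_branch(self):
        dp = P.DamageParams()
        rep = P.critical_ratio(dp, 1.0, 1.0)
        assert rep.a2_star == pytest.approx(dp.a_max - dp.c_tau / dp.c_beta)
        assert rep.a1_stable and not rep.a2_stable  # R = 1 > R_crit

    def test_zero_amyloid_damage_flagged(self):
        rep = P.critical_ratio(P.DamageParams(), 0.0, 0.4)
        assert not rep.R_defined and np.isnan(rep.R)

    @pytest.mark.parametrize("qb,qt", [(0.6, 0.2), (0.3, 0.2), (0.5, 0.7), (0.9, 0.9)])
    def test_stability_against_ode_oracle(self, qb, qt):
        """Forward integration of the scalar a-equation decides stability."""
        dp = P.DamageParams()
        rep = P.critical_ratio(dp, qb, qt)
        rhs = lambda t, a: (dp.c_beta * qb * (dp.a_max - a) - dp.c_tau * qt) * (a - dp.a_min)
        a_inf = solve_ivp(rhs, (0, 2000), [dp.a_min + 0.02], rtol=1e-10, atol=1e-13).y[0, -1]
        target = rep.a1_star if rep.R > rep.R_crit else rep.a2_star
        assert a_inf == pytest.approx(target, abs=1e-6)


class TestLobeAverage:
    def test_uniform_field_and_locality(self, small_connectome):
        s = P.initialize_state(small_connectome)
        series = P.SnapshotSeries(np.array([0.0]), [s])
        table = P.lobe_average(series, small_connectome, "u")
        assert np.allclose(table.to_numpy(), 1.0)

        s2 = s.copy()
        limbic = np.nonzero(small_connectome.lobes == "limbic")[0]
        s2.u[limbic] += 1.0
        t2 = P.lobe_average(
            P.SnapshotSeries(np.array([0.0]), [s2]), small_connectome, "u"
        )
        changed = [
            col for col in t2.columns
            if col != "global" and not np.allclose(t2[col], table[col])
        ]
        assert changed == ["limbic"]

    def test_tau_reaches_limbic_before_occipital(self, small_connectome, default_series):
        """Entorhinal-seeded tau invades its own lobe before the far neocortex."""
        table = P.lobe_average(default_series, small_connectome, "v_toxic")
        threshold = 0.1
        first = {
            lobe: np.argmax(table[lobe].to_numpy() > threshold)
            for lobe in ("limbic", "occipital")
        }
        assert first["limbic"] < first["occipital"]

    def test_unknown_field_rejected(self, small_connectome, default_series):
        with pytest.raises(Exception):
            P.lobe_average(default_series, small_connectome, "nope")
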