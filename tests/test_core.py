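"""Core formulations: binding solver, conservation, reductions, nullclines."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cccsim import (CCCParams, ConservedTriple, conserved_quantities,
                    free_carrier, integrate, nullclines, rhs_full,
                    rhs_reduced2, rhs_reduced5, steady_state)
from cccsim.core import (IntegrationError, full_state_from_reduced,
                         project_full_state)
from cccsim.jamming import initial_state_jam, kin_threshold

from conftest import random_params


class TestFreeCarrier:
    @pytest.mark.parametrize("total,partner,K,expected", [
        (2.0, 0.0, 1.0, 2.0),                 # no partner: all free
        (2.0, 1.0, 1.0, np.sqrt(2.0)),        # hand-solved quadratic
    ])
    def test_known_roots(self, total, partner, K, expected):
        assert free_carrier(total, partner, K) == pytest.approx(expected, rel=1e-12)

    def test_perfect_binding_limit(self):
        # partner in excess, tiny K: essentially everything bound
        assert free_carrier(1.0, 10.0, 1e-6) <= 1e-6

    def test_rejects_nonpositive_K(self):
        with pytest.raises(ValueError):
            free_carrier(1.0, 1.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(total=st.floats(0.0, 1e4), partner=st.floats(0.0, 1e4),
           K=st.floats(1e-8, 1e3))
    def test_implicit_total_equation(self, total, partner, K):
        """The root always satisfies total = x + partner*x/(K+x), x in [0, total]."""
        x = free_carrier(total, partner, K)
        assert 0.0 <= x <= total * (1 + 1e-12)
        recon = x + partner * x / (K + x)
        assert recon == pytest.approx(total, rel=1e-9, abs=1e-12)


class TestConservedQuantities:
    def test_reduced5_sums(self):
        c = conserved_quantities(
            {"m0": 0.0, "m1": 0.3, "m2": 0.0, "c_t": 1.5, "cstar_t": 0.5},
            "reduced5")
        assert (c.cpool, c.csum, c.cdiff_star) == (2.0, 1.8, pytest.approx(0.2))

    def test_identity_cpool_csum_cdiff(self, rng):
        for _ in range(20):
            ct, cst, m1 = rng.uniform(0, 3, 3)
            c = conserved_quantities(
                {"m0": 1.0, "m1": m1, "m2": 0.0, "c_t": ct, "cstar_t": cst},
                "reduced5")
            assert c.cpool == pytest.approx(c.csum + c.cdiff_star)

    def test_full_model_totals_include_complexes(self):
        state = {"m0": 0.0, "m1": 0.3, "m2": 0.0, "c": 0.9, "cstar": 0.8,
                 "cm0": 0.1, "cstarm1": 0.2}
        c = conserved_quantities(state, "full")
        assert c.cpool == pytest.approx(2.0)
        # csum counts complexed m1 (c*.m1) as well: this is the quantity
        # the mass-action dynamics conserve exactly
        assert c.csum == pytest.approx(0.9 + 0.1 + 0.3 + 0.2)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            conserved_quantities(
                {"m0": -1.0, "m1": 0, "m2": 0, "c_t": 1, "cstar_t": 1},
                "reduced5")


class TestRhsFull:
    def test_empty_system_influx_only(self):
        p = CCCParams(kin=1.0)
        d = rhs_full(np.zeros(7), p)
        assert d[0] == 1.0
        assert np.all(d[1:] == 0.0)

    def test_carrier_and_csum_conserved_on_random_states(self, rng):
        p = random_params(rng, kleak=0.3)
        for _ in range(25):
            y = rng.uniform(0, 2, 7)
            d = rhs_full(y, p)
            # symbolically zero; float cancellation is relative to the
            # largest (binding) propensities ~ ka * c * m
            tol = 1e-13 * max(p.ka0, p.ka1) * 4.0
            # d(c + cm0 + c* + c*m1)/dt = 0 (carrier pool)
            assert d[3] + d[4] + d[5] + d[6] == pytest.approx(0.0, abs=tol)
            # d(c + cm0 + m1 + c*m1)/dt = 0 (csum)
            assert d[3] + d[5] + d[1] + d[6] == pytest.approx(0.0, abs=tol)

    def test_steady_state_root(self, rng):
        from scipy.optimize import fsolve
        p = CCCParams(kin=0.5, kleak=0.1, ka0=1e3, ka1=1e3)
        y0 = np.array([0.5, 0.5, 0.5, 1.0, 0.5, 0.25, 0.25])
        root = fsolve(lambda y: rhs_full(y, p), y0, full_output=False)
        assert np.max(np.abs(rhs_full(root, p))) <= 1e-10


class TestRhsReduced5:
    def test_no_active_carrier_no_consumption(self, params):
        d = rhs_reduced5(np.array([1.0, 0.5, 0.0, 0.0, 2.0]), params)
        # v_c = 0: dm0 = kin, dm1 = -v_p <= 0
        assert d[0] == pytest.approx(params.kin)
        assert d[1] <= 0.0

    def test_conservation_by_construction(self, rng, params):
        for _ in range(20):
            y = rng.uniform(0, 3, 5)
            d = rhs_reduced5(y, params)
            assert d[3] + d[4] == pytest.approx(0.0, abs=1e-14)   # cpool
            assert d[3] + d[1] == pytest.approx(0.0, abs=1e-14)   # csum

    def test_matches_full_model_in_adiabatic_limit(self, rng, params):
        p = params.replace(ka0=1e6, ka1=1e6)
        for _ in range(10):
            y5 = np.array([rng.uniform(0, 5), 0.0, rng.uniform(0, 2),
                           rng.uniform(0.1, 1.9), 0.0])
            y5[4] = 2.0 - y5[3]
            y5[1] = rng.uniform(0, 0.5)
            yf = full_state_from_reduced(y5, p)
            df = rhs_full(yf, p)
            proj = np.array([df[0] + df[5], df[1] + df[6], df[2],
                             df[3] + df[5], df[4] + df[6]])
            assert np.max(np.abs(proj - rhs_reduced5(y5, p))) <= 1e-6


class TestRhsReduced2:
    def test_trajectory_matches_reduced5(self, params, conserved):
        t2 = integrate("reduced2", [5.0, 0.0], params, t_end=50.0,
                       sample_dt=0.5, conserved=conserved)
        t5 = integrate("reduced5", initial_state_jam(conserved, 5.0), params,
                       t_end=50.0, sample_dt=0.5)
        dev = np.abs(t2.frame[["m0", "m1"]].to_numpy()
                     - t5.frame[["m0", "m1"]].to_numpy())
        assert dev.max() <= 1e-6

    def test_m0_nullcline_value(self, params, conserved):
        # with m1 on the m1-nullcline and m0 from the m0-nullcline, dm0/dt = 0
        nc = nullclines(params, conserved, [0.5])
        m0 = nc.m0_nullcline[0]
        dm0, _ = rhs_reduced2(m0, 0.5, params, conserved)
        assert dm0 == pytest.approx(0.0, abs=1e-9)

    def test_supercritical_influx_always_grows(self, conserved):
        p = CCCParams(kin=1.2, kleak=0.0)
        traj = integrate("reduced2", [0.0, 0.0], p, t_end=200.0,
                         sample_dt=1.0, conserved=conserved)
        dm0 = np.diff(traj.frame["m0"].to_numpy()[50:])
        assert np.all(dm0 > 0)

    def test_m1_above_csum_rejected(self, params, conserved):
        with pytest.raises(ValueError):
            rhs_reduced2(1.0, conserved.csum + 0.1, params, conserved)


class TestIntegrate:
    def test_subcritical_run_converges(self, conserved):
        p = CCCParams(kin=0.9, kleak=0.0)
        traj = integrate("reduced5", initial_state_jam(conserved, 100.0), p,
                         t_end=1500.0)
        last = traj.frame.iloc[-1]
        d = rhs_reduced5(last[["m0", "m1", "m2", "c_t", "cstar_t"]].to_numpy(), p)
        assert np.max(np.abs(d)) <= 1e-6

    def test_zero_influx_drains(self, conserved):
        p = CCCParams(kin=0.0, kleak=0.0)
        traj = integrate("reduced5", initial_state_jam(conserved, 5.0), p,
                         t_end=1000.0)
        last = traj.frame.iloc[-1]
        assert last[["m0", "m2"]].max() <= 1e-8
        # m1 empties through an algebraically slow tail (the regenerating
        # flux is ~ kp m1^2/K1 once the inactive carrier is scarce)
        assert last["m1"] <= 10 * p.K1 / (p.kp * traj.times[-1])
        assert last["c_t"] == pytest.approx(conserved.csum, abs=1e-5)

    def test_conservation_drift_long_run(self, conserved):
        p = CCCParams(kin=0.95, kleak=0.0)
        traj = integrate("reduced5", initial_state_jam(conserved, 100.0), p,
                         t_end=3000.0)
        cpool = traj.frame["c_t"] + traj.frame["cstar_t"]
        csum = traj.frame["c_t"] + traj.frame["m1"]
        assert np.max(np.abs(cpool - conserved.cpool)) <= 1e-8 * conserved.cpool
        assert np.max(np.abs(csum - conserved.csum)) <= 1e-8 * conserved.csum

    def test_first_state_is_initial_state(self, params, conserved):
        y0 = initial_state_jam(conserved, 7.0)
        traj = integrate("reduced5", y0, params, t_end=10.0)
        np.testing.assert_allclose(
            traj.frame[["m0", "m1", "m2", "c_t", "cstar_t"]].iloc[0], y0)

    def test_invalid_grid_rejected(self, params, conserved):
        with pytest.raises(ValueError):
            integrate("reduced5", initial_state_jam(conserved), params,
                      t_end=-1.0)


class TestAdiabaticConvergence:
    def test_discrepancy_decreases_with_ka(self, conserved):
        p = CCCParams(kin=0.9, kleak=0.0)
        y5 = initial_state_jam(conserved, 5.0)
        t5 = integrate("reduced5", y5, p, t_end=50.0, sample_dt=0.5)
        devs = []
        for ka in (1e2, 1e4, 1e6):
            pk = p.replace(ka0=ka, ka1=ka)
            tf = integrate("full", full_state_from_reduced(y5, pk), pk,
                           t_end=50.0, sample_dt=0.5)
            m0 = tf.frame["m0"] + tf.frame["cm0"]
            m1 = tf.frame["m1"] + tf.frame["cstarm1"]
            scale = max(1.0, float(m0.max()))
            devs.append(max(np.max(np.abs(m0 - t5.frame["m0"])) / scale,
                            np.max(np.abs(m1 - t5.frame["m1"]))))
        assert devs[0] > devs[1] > devs[2]
        assert devs[2] <= 2e-4


class TestNullclines:
    def test_subcritical_crossing_equals_steady_state(self, conserved):
        p = CCCParams(kin=0.8, kleak=0.0)
        ss = steady_state(p, conserved)
        assert ss is not None
        nc = nullclines(p, conserved, [ss["m1"]])
        assert nc.m0_nullcline[0] == pytest.approx(ss["m0"], rel=1e-6)
        assert nc.m1_nullcline[0] == pytest.approx(ss["m0"], rel=1e-6)

    def test_supercritical_no_crossing(self, conserved):
        p = CCCParams(kin=1.2, kleak=0.0)
        grid = np.linspace(1e-6, conserved.csum * 0.999, 120)
        nc = nullclines(p, conserved, grid)
        diff = nc.m0_nullcline - nc.m1_nullcline
        ok = np.isfinite(diff)
        # wherever both exist the nullclines keep a fixed ordering
        assert np.all(diff[ok] > 0) or np.all(diff[ok] < 0)
        assert steady_state(p, conserved) is None

    def test_leak_tilts_nullcline_and_restores_fixed_point(self, conserved):
        p = CCCParams(kin=1.2, kleak=0.05)
        ss = steady_state(p, conserved)
        assert ss is not None
        dm0, dm1 = rhs_reduced2(ss["m0"], ss["m1"], p, conserved)
        assert max(abs(dm0), abs(dm1)) <= 1e-10

    def test_grid_outside_domain_rejected(self, params, conserved):
        with pytest.raises(ValueError):
            nullclines(params, conserved, [conserved.csum + 1.0])


class TestSteadyState:
    def test_flux_balance_at_fixed_point(self, conserved):
        p = CCCParams(kin=0.7, kleak=0.0)
        ss = steady_state(p, conserved)
        assert ss["vc"] == pytest.approx(p.kin, rel=1e-6)
        assert ss["vp"] == pytest.approx(p.kin, rel=1e-6)

    def test_none_above_threshold_without_leak(self, conserved):
        p = CCCParams(kin=1.1, kleak=0.0)
        assert steady_state(p, conserved) is None

    def test_exists_above_threshold_with_leak(self, conserved):
        p = CCCParams(kin=1.1, kleak=1e-3)
        ss = steady_state(p, conserved)
        assert ss is not None
        kin_th = kin_threshold(p.replace(kleak=0.0), conserved.cpool,
                               conserved.csum)
        # the leak absorbs the excess influx: m0* ~ (kin - kin_th)/kleak
        assert ss["m0"] == pytest.approx((p.kin - kin_th) / p.kleak, rel=0.1)
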