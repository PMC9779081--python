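"""Six-compartment model: assembly, dynamics, decomposition, sweeps."""

import numpy as np
import pytest
from scipy.linalg import expm

from immunopk.data_tables import blood_pk_params
from immunopk.errors import InvalidStateError, MissingParameterError
from immunopk.sixcomp import (
    PhenotypeMap,
    ScalingPolicy,
    SixCompartmentParams,
    assemble_params,
    delivery_metrics,
    passive_only_scenario,
    rate_matrix,
    retention_decomposition,
    rhs,
    simulate,
    sweep,
)
from immunopk.two_compartment import xb_analytic, xp_analytic

from conftest import random_sixcomp_params


def expm_oracle(params, times):
    """Matrix-exponential solution, independent of the ODE stepper."""
    A = rate_matrix(params)
    x0 = np.zeros(7)
    x0[0] = params.X0
    return np.array([expm(A * t) @ x0 for t in times])


class TestAssembly:
    def test_tumor_exchange_scaling(self, rate_table):
        """K_bt and K_tb are 0.05% of the peripheral exchange rates."""
        params = assemble_params(blood_pk_params(100), rate_table, "BNF-Plain")
        assert params.K_bt == pytest.approx(0.0088, abs=5e-5)
        assert params.K_tb == pytest.approx(0.0011, abs=5e-5)

    def test_macrophage_rates_follow_phenotype_map(self, rate_table):
        params = assemble_params(blood_pk_params(100), rate_table, "BNF-Plain")
        assert params.K_bm == pytest.approx(0.00092)  # M0 in blood
        assert params.K_mb == pytest.approx(0.11562)
        assert params.K_pm == params.K_tm == pytest.approx(0.00101)  # M1
        assert params.K_mp == params.K_mt == 0.0

    def test_alternate_phenotype_map(self, rate_table):
        params = assemble_params(
            blood_pk_params(100),
            rate_table,
            "BNF-Her",
            pheno_map=PhenotypeMap(blood="M0", peripheral="M2", tumor="M1"),
        )
        assert params.K_pm == pytest.approx(0.00102)  # BNF-Her M2
        assert params.K_tm == pytest.approx(0.00238)  # BNF-Her M1

    def test_missing_entry_raises(self, rate_table):
        with pytest.raises(MissingParameterError):
            assemble_params(blood_pk_params(100), rate_table, "BNF-Unknown")

    def test_scaled_rates_never_exceed_peripheral(self, rate_table):
        params = assemble_params(
            blood_pk_params(30), rate_table, "BNF-IgG", policy=ScalingPolicy(y=0.01)
        )
        assert params.K_bt <= params.K_bp
        assert params.K_tb <= params.K_pb


class TestRHS:
    def test_initial_state_derivatives(self, headline_params):
        p = headline_params
        d = rhs([100.0, 0, 0, 0, 0, 0], p)
        assert d[0] == pytest.approx(
            -(p.K_el + p.K_bp + p.K_bt + p.k_b * p.K_bm) * 100.0
        )
        assert d[1] == pytest.approx(p.K_bp * 100.0)
        assert d[2] == pytest.approx(p.K_bt * 100.0)
        assert d[3] == pytest.approx(p.k_b * p.K_bm * 100.0)
        assert d[4] == d[5] == 0.0

    def test_summed_derivatives_equal_elimination_flux(self):
        """The only mass sink is elimination from free blood nanoparticles."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = random_sixcomp_params(rng)
            state = rng.uniform(0, 30, 6)
            d = rhs(state, p)
            assert d.sum() == pytest.approx(-p.K_el * state[0], rel=1e-9, abs=1e-12)

    def test_all_rates_zero_gives_zero_derivatives(self):
        p = SixCompartmentParams(*([0.0] * 11), k_b=0, k_p=0, k_t=0)
        np.testing.assert_array_equal(rhs(np.ones(6), p), np.zeros(6))

    def test_negative_state_rejected(self, headline_params):
        with pytest.raises(InvalidStateError):
            rhs([-1.0, 0, 0, 0, 0, 0], headline_params)

    def test_generator_columns_sum_to_zero(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            A = rate_matrix(random_sixcomp_params(rng))
            np.testing.assert_allclose(A.sum(axis=0), 0.0, atol=1e-12)


class TestSimulate:
    def test_headline_scenario_endpoints(self, headline_params):
        """100-nm BNF-Plain with k=40: about 1 %ID tumor and 40 %ID peripheral at 48 h."""
        traj = simulate(headline_params)
        assert traj.tumor_total[-1] == pytest.approx(1.0, rel=0.3)
        assert traj.peripheral_total[-1] == pytest.approx(40.0, rel=0.3)

    def test_mass_conservation(self, headline_params):
        traj = simulate(headline_params)
        assert np.max(np.abs(traj.total_mass() - 100.0)) <= 1e-6

    def test_matches_matrix_exponential_oracle(self, headline_params):
        times = [1.0, 12.0, 48.0]
        traj = simulate(headline_params, t_end=48.0, n_points=49,
                        rtol=1e-11, atol=1e-13)
        ref = expm_oracle(headline_params, times)
        for t, r in zip(times, ref):
            i = int(t)  # grid spacing is 1 h
            got = np.array(
                [traj.xb[i], traj.xp[i], traj.xt[i], traj.mb[i], traj.mp[i],
                 traj.mt[i], traj.eliminated[i]]
            )
            np.testing.assert_allclose(got, r, rtol=1e-8, atol=1e-10)

    def test_oracle_on_random_parameter_draws(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = random_sixcomp_params(rng)
            traj = simulate(p, t_end=48.0, n_points=5, rtol=1e-11, atol=1e-13)
            ref = expm_oracle(p, traj.times[1:])
            got = np.stack(
                [traj.xb, traj.xp, traj.xt, traj.mb, traj.mp, traj.mt,
                 traj.eliminated], axis=1
            )[1:]
            np.testing.assert_allclose(got, ref, rtol=1e-7, atol=1e-8)

    def test_reduction_to_two_compartment_analytics(self, rate_table):
        """k=0 and no tumor exchange: xb, xp match the closed-form solutions."""
        tc = blood_pk_params(100)
        params = assemble_params(
            tc, rate_table, "BNF-Plain", policy=ScalingPolicy(y=0.0),
            k_factors=(0.0, 0.0, 0.0),
        )
        traj = simulate(params)
        np.testing.assert_allclose(
            traj.xb, np.asarray(xb_analytic(tc, traj.times)), rtol=1e-6, atol=1e-8
        )
        np.testing.assert_allclose(
            traj.xp, np.asarray(xp_analytic(tc, traj.times)), rtol=1e-6, atol=1e-8
        )
        assert np.all(traj.xt == 0) and np.all(traj.mt == 0)

    def test_three_compartment_reduction_keeps_macrophages_empty(self, rate_table):
        params = assemble_params(
            blood_pk_params(100), rate_table, "BNF-Plain", k_factors=(0.0, 0.0, 0.0)
        )
        traj = simulate(params)
        assert np.all(traj.mb == 0) and np.all(traj.mp == 0) and np.all(traj.mt == 0)
        # and the tumor pool is fed passively
        assert traj.xt[-1] > 0

    def test_linearity_in_injected_dose(self, headline_params):
        from dataclasses import replace

        traj1 = simulate(headline_params, n_points=25, rtol=1e-11, atol=1e-13)
        traj3 = simulate(replace(headline_params, X0=300.0), n_points=25,
                         rtol=1e-11, atol=1e-13)
        for name in ("xb", "xp", "xt", "mb", "mp", "mt", "eliminated"):
            np.testing.assert_allclose(
                getattr(traj3, name), 3.0 * getattr(traj1, name),
                rtol=1e-10, atol=1e-12,
            )

    def test_nonnegative_states_on_random_draws(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            traj = simulate(random_sixcomp_params(rng), n_points=97)
            for name in ("xb", "xp", "xt", "mb", "mp", "mt", "eliminated"):
                assert np.all(getattr(traj, name) >= 0)

    def test_absorbing_macrophage_pools_are_monotone(self, headline_params):
        # K_mt = K_mp = 0 in the headline set: internalized pools never shrink
        traj = simulate(headline_params)
        assert np.all(np.diff(traj.mt) >= -1e-10)
        assert np.all(np.diff(traj.mp) >= -1e-10)

    def test_solver_grid_and_initial_conditions(self, headline_params):
        traj = simulate(headline_params, t_end=24.0, n_points=49)
        assert traj.times[0] == 0.0 and traj.times[-1] == 24.0
        assert traj.xb[0] == 100.0
        assert traj.eliminated[0] == 0.0


class TestDecompositionAndMetrics:
    def test_totals_are_exact_sums(self, headline_params):
        traj = simulate(headline_params)
        dec = retention_decomposition(traj)
        for comp in ("blood", "peripheral", "tumor"):
            np.testing.assert_array_equal(
                dec[f"{comp}_total"], dec[f"{comp}_passive"] + dec[f"{comp}_active"]
            )

    def test_no_macrophages_means_no_active_retention(self, rate_table):
        params = assemble_params(
            blood_pk_params(100), rate_table, "BNF-Plain", k_factors=(0, 0, 0)
        )
        dec = retention_decomposition(simulate(params))
        assert np.all(dec["tumor_active"] == 0)
        assert np.all(dec["peripheral_active"] == 0)

    def test_active_retention_overtakes_passive(self, headline_params):
        """Macrophage-internalized content overtakes the free pool: in the
        peripheral compartment about half a day after injection, in the
        tumor during the second day, and both dominate by 48 h."""
        traj = simulate(headline_params)
        assert np.all(traj.mp[traj.times > 14.0] > traj.xp[traj.times > 14.0])
        assert np.all(traj.mt[traj.times > 27.0] > traj.xt[traj.times > 27.0])
        assert traj.mt[-1] > traj.xt[-1] and traj.mp[-1] > traj.xp[-1]

    def test_metrics_consistent_with_trajectory(self, headline_params):
        traj = simulate(headline_params)
        m = delivery_metrics(traj)
        assert m.tumor_total_end == pytest.approx(traj.tumor_total[-1])
        assert m.peripheral_total_end == pytest.approx(traj.peripheral_total[-1])
        # tumor retention is still rising at 48 h in this scenario
        assert m.tumor_peak_time == pytest.approx(48.0)
        assert m.tumor_peak >= m.tumor_total_end

    def test_peak_refinement_on_interior_maximum(self):
        # a scenario with fast tumor exchange and strong efflux peaks early
        p = SixCompartmentParams(
            K_el=0.5, K_bp=5.0, K_pb=0.5, K_bt=0.5, K_tb=2.0,
            K_bm=0, K_mb=0, K_pm=0, K_mp=0, K_tm=0, K_mt=0,
            k_b=0, k_p=0, k_t=0,
        )
        m = delivery_metrics(simulate(p))
        assert 0.0 < m.tumor_peak_time < 48.0
        assert m.tumor_peak > m.tumor_total_end


class TestSweepAndScenarios:
    def test_identity_factor_reproduces_base(self, headline_params):
        base = simulate(headline_params, n_points=25)
        fam = sweep(headline_params, "K_pb", [1.0], n_points=25)
        np.testing.assert_array_equal(fam[0].tumor_total, base.tumor_total)

    def test_increasing_k_pb_raises_tumor_delivery(self, headline_params):
        fam = sweep(headline_params, "K_pb", [1.0, 2.0, 5.0], n_points=49)
        ends = [t.tumor_total[-1] for t in fam]
        assert ends == sorted(ends)

    def test_decreasing_k_pm_lowers_peripheral_retention(self, headline_params):
        fam = sweep(headline_params, "K_pm", [1.0, 0.5, 0.1], n_points=49)
        ends = [t.peripheral_total[-1] for t in fam]
        assert ends == sorted(ends, reverse=True)

    def test_base_params_not_mutated(self, headline_params):
        before = headline_params.K_pb
        sweep(headline_params, "K_pb", [3.0], n_points=9)
        assert headline_params.K_pb == before

    def test_passive_only_matches_three_compartment_reduction(self, rate_table):
        tc = blood_pk_params(100)
        traj = passive_only_scenario(tc, y=0.0005, n_points=49)
        params = assemble_params(
            tc, rate_table, "BNF-Plain", policy=ScalingPolicy(y=0.0005),
            k_factors=(0, 0, 0),
        )
        ref = simulate(params, n_points=49)
        np.testing.assert_allclose(traj.xt, ref.xt, rtol=1e-9, atol=1e-12)
        np.testing.assert_allclose(traj.xp, ref.xp, rtol=1e-9, atol=1e-12)

    def test_passive_high_y_clears_fast_with_low_peripheral_uptake(
        self, headline_params
    ):
        """The y=0.44 passive-only scenario trades peripheral retention for clearance."""
        tc = blood_pk_params(100)
        passive = passive_only_scenario(tc, y=0.44)
        active = simulate(headline_params)
        assert passive.peripheral_total[-1] < active.peripheral_total[-1]
        assert passive.eliminated[-1] > active.eliminated[-1]

    def test_zero_tumor_exchange_keeps_tumor_empty(self):
        tc = blood_pk_params(100)
        traj = passive_only_scenario(tc, y=0.0, n_points=25)
        assert np.all(traj.xt == 0) and np.all(traj.mt == 0)
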