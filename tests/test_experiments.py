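"""Grid scans, run selection, sweeps, decomposition and envelopes."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import tumorshed as ts
from tumorshed.experiments import (
    DEFAULT_SCAN_PSI,
    DEFAULT_SCAN_THALF,
    DEFAULT_SCAN_UH,
    EnvelopeResult,
    ScanResult,
    ValidityCriteria,
    grid_scan_growth,
    growth_inflection_day,
    per_compartment_decomposition,
    protein_scan_envelopes,
    select_valid_run,
    sensitivity_sweep,
)
from tumorshed.oxygen_rates import compartment_rate_table
from tumorshed.shedding import ProteinParams


def _scan_result(rows):
    return ScanResult(table=pd.DataFrame(rows), criteria=ValidityCriteria())


class TestSelectValidRun:
    def test_single_valid_pair(self):
        scan = _scan_result([
            {"k_v": 0.1, "c0": 16.0, "final_population": 2e7,
             "populated_compartments": 10, "valid": True, "reason": ""},
        ])
        assert select_valid_run(scan) == (0.1, 16.0)

    def test_argmin_population(self):
        scan = _scan_result([
            {"k_v": 0.1, "c0": 16.0, "final_population": 5e7,
             "populated_compartments": 10, "valid": True, "reason": ""},
            {"k_v": 0.2, "c0": 12.0, "final_population": 2e7,
             "populated_compartments": 10, "valid": True, "reason": ""},
        ])
        assert select_valid_run(scan) == (0.2, 12.0)

    def test_tie_breaks_on_smaller_kv_then_c0(self):
        scan = _scan_result([
            {"k_v": 0.2, "c0": 8.0, "final_population": 2e7,
             "populated_compartments": 10, "valid": True, "reason": ""},
            {"k_v": 0.1, "c0": 16.0, "final_population": 2e7,
             "populated_compartments": 10, "valid": True, "reason": ""},
            {"k_v": 0.1, "c0": 8.0, "final_population": 2e7,
             "populated_compartments": 10, "valid": True, "reason": ""},
        ])
        assert select_valid_run(scan) == (0.1, 8.0)

    def test_no_valid_tumor(self):
        scan = _scan_result([
            {"k_v": 0.0, "c0": 16.0, "final_population": 0.0,
             "populated_compartments": 0, "valid": False, "reason": "x"},
        ])
        assert select_valid_run(scan) is None


class TestGridScan:
    def test_degenerate_kv_marked_invalid_not_crash(self, default_cfg):
        crit = ValidityCriteria(t_end_days=200)
        result = grid_scan_growth([0.0, 0.05], [16.0], crit, default_cfg)
        row0 = result.table.iloc[0]
        assert row0["k_v"] == 0.0 and not row0["valid"]
        assert len(result.table) == 2

    def test_scan_is_deterministic(self, default_cfg):
        crit = ValidityCriteria(t_end_days=300)
        a = grid_scan_growth([0.05, 0.1], [8.0, 16.0], crit, default_cfg)
        b = grid_scan_growth([0.05, 0.1], [8.0, 16.0], crit, default_cfg)
        pd.testing.assert_frame_equal(a.table, b.table)


class TestSensitivitySweep:
    def test_unknown_parameter_lists_valid_names(self, default_cfg):
        with pytest.raises(ValueError, match="k_v"):
            sensitivity_sweep("bogus", [1.0], default_cfg)

    def test_single_value_sweep_equals_plain_run(self, default_cfg):
        cfg = dataclasses.replace(
            default_cfg,
            simulation=dataclasses.replace(default_cfg.simulation, t_end_days=300),
        )
        [entry] = sensitivity_sweep("k_v", [cfg.vascular.k_v], cfg)
        plain = ts.run_growth(cfg)
        assert np.array_equal(entry.growth.P, plain.P)

    def test_thalf_family_ordered_pointwise(self, baseline_cfg):
        cfg = dataclasses.replace(
            baseline_cfg,
            simulation=dataclasses.replace(
                baseline_cfg.simulation, t_end_days=400
            ),
            proteins=(ProteinParams(name="p", ec=0, psi=4.5e-4, u_h=456.0, q0=0.0),),
        )
        entries = sensitivity_sweep(
            "t_half", [0.64, 6.4, 640.0], cfg, mode="shedding"
        )
        qs = [e.shedding["p"].q for e in entries]
        assert np.all(qs[0] <= qs[1] + 1e-9)
        assert np.all(qs[1] <= qs[2] + 1e-9)
        # growth-side cache: same growth trajectory object reused
        assert entries[0].growth is entries[1].growth


class TestDecomposition:
    def test_shares_sum_to_one_and_totals_exact(self, short_growth, default_rates):
        shed = ts.simulate_shedding(
            short_growth, default_rates, ProteinParams(ec=1, phi=4.5e-4)
        )
        df = per_compartment_decomposition(short_growth, shed)
        g = df.groupby("t_day")
        p_sum = g["P"].sum().to_numpy()
        assert np.allclose(p_sum, short_growth.total_P, rtol=1e-12)
        share_sum = g["P_share"].sum().to_numpy()
        mask = short_growth.total_P > 0
        assert np.allclose(share_sum[mask], 1.0, rtol=1e-9)
        u_share = g["u_share"].sum().to_numpy()
        assert np.allclose(u_share[shed.u_total > 0], 1.0, rtol=1e-9)

    def test_innermost_dominates_population_early(self, short_growth, default_rates):
        df = per_compartment_decomposition(short_growth)
        early = df[(df["t_day"] == 100)]
        assert early.loc[early["comp"] == 1, "P_share"].iloc[0] > 0.5

    def test_outer_death_share_exceeds_population_share_late(
        self, baseline_growth_12y
    ):
        df = per_compartment_decomposition(baseline_growth_12y)
        late = df[df["t_day"] == int(baseline_growth_12y.t[-1])]
        outer = late[late["comp"] >= 8]
        assert outer["D_share"].sum() > outer["P_share"].sum()


@pytest.fixture(scope="module")
def envelopes(short_growth, default_cfg):
    rates = compartment_rate_table(
        default_cfg.spatial, default_cfg.oxygen, default_cfg.anchors
    )
    ec_ref = ProteinParams(name="ec", ec=1, phi=4.5e-4, u_h=456.0,
                           t_half_days=6.4)
    return protein_scan_envelopes(short_growth, rates, ec_reference=ec_ref)


class TestProteinScanEnvelopes:
    def test_bounds_equal_brute_force_extremes(self, envelopes):
        """Pointwise min/max over the grid equals the stored envelopes."""
        for env in envelopes:
            stack = np.stack(list(env.grid.values()))
            assert np.array_equal(env.q_min, stack.min(axis=0))
            assert np.array_equal(env.q_max, stack.max(axis=0))

    def test_bounds_achieved_at_corner_trajectories(self, envelopes):
        """Monotonicity puts the envelope on the (min,min)/(max,max) corners."""
        for env in envelopes:
            lo = env.grid[(min(DEFAULT_SCAN_PSI), min(DEFAULT_SCAN_THALF))]
            hi = env.grid[(max(DEFAULT_SCAN_PSI), max(DEFAULT_SCAN_THALF))]
            check = np.linspace(0, len(lo) - 1, 10).astype(int)
            assert np.allclose(env.q_min[check], lo[check], rtol=1e-12)
            assert np.allclose(env.q_max[check], hi[check], rtol=1e-12)
            assert env.corner_min == (min(DEFAULT_SCAN_PSI), min(DEFAULT_SCAN_THALF))
            assert env.corner_max == (max(DEFAULT_SCAN_PSI), max(DEFAULT_SCAN_THALF))

    def test_boosted_nonec_overtakes_ec_reference(self, envelopes):
        """At the large-psi/long-half-life corner the non-EC protein wins."""
        env456 = next(e for e in envelopes if e.u_h == 4.56e2)
        assert env456.crossover_day is not None

    def test_single_point_grid_degenerates(self, short_growth, default_cfg):
        rates = compartment_rate_table(
            default_cfg.spatial, default_cfg.oxygen, default_cfg.anchors
        )
        [env] = protein_scan_envelopes(
            short_growth, rates, psi_values=[1.0], uh_values=[456.0],
            thalf_values=[6.4],
        )
        assert np.array_equal(env.q_min, env.q_max)


class TestInflectionDetector:
    def test_synthetic_two_phase_trajectory(self):
        """Exponential phase then stall: detector lands at the break."""
        T = 1200
        t = np.arange(T)
        g = 5e-3
        logp = np.where(t < 800, g * t, g * 800 + 1e-4 * (t - 800))
        traj = ts.GrowthTrajectory(
            t=t, P=np.exp(logp)[:, None] * np.ones((T, 1)),
            B_inst=np.zeros((T, 1)), D_inst=np.zeros((T, 1)),
            D_cum=np.zeros((T, 1)), K=np.zeros((T, 1)), h_mm=np.zeros(T),
        )
        day = growth_inflection_day(traj)
        assert 800 <= day <= 830  # within one trailing window of the break

    def test_pure_exponential_has_no_inflection(self):
        T = 500
        t = np.arange(T)
        traj = ts.GrowthTrajectory(
            t=t, P=np.exp(4e-3 * t)[:, None], B_inst=np.zeros((T, 1)),
            D_inst=np.zeros((T, 1)), D_cum=np.zeros((T, 1)),
            K=np.zeros((T, 1)), h_mm=np.zeros(T),
        )
        with pytest.raises(ValueError, match="transition"):
            growth_inflection_day(traj)
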