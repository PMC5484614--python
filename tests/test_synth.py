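"""Generator correctness: presets, determinism, circuit physics, cohorts."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

from opclamp.sweeps import SimulationError
from opclamp.synth import (
    DrugEvent,
    PRESETS,
    bath_protocol,
    get_preset,
    make_cell,
    probe_protocol,
    random_walk_internode,
    rr_protocol,
    simulate_caspase_cohort,
    simulate_fiber_geometry,
    simulate_histology_counts,
    simulate_voltage_clamp,
    step_protocol,
)
from opclamp.synth.protocols import ProtocolSpec, STEP_VOLTAGES_MV


class TestPresets:
    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown genotype preset"):
            get_preset("quadruple-ko")

    def test_planted_effect_sizes(self):
        assert PRESETS["dko"].kainate_density_rel == pytest.approx(0.53)
        assert PRESETS["tko"].kainate_density_rel == pytest.approx(0.23 * 0.53)
        assert PRESETS["control"].ampar_fraction == PRESETS["dko"].ampar_fraction == 0.80
        assert PRESETS["tko"].ampar_fraction == 0.39
        assert PRESETS["dko"].synapse_rate_rel == 0.30

    def test_epsc_amplitude_genotype_invariant(self):
        # knockouts change synapse number, never quantal amplitude
        amps = {
            (p.epsc_amplitude_mean_pa, p.epsc_amplitude_sd_pa) for p in PRESETS.values()
        }
        assert len(amps) == 1

    def test_only_dko_rectifies(self):
        assert PRESETS["dko"].ampar_rectifying
        assert not PRESETS["control"].ampar_rectifying
        assert not PRESETS["tko"].ampar_rectifying


class TestMakeCell:
    @pytest.mark.parametrize("preset", ["control", "dko", "tko"])
    def test_cells_satisfy_op_criteria(self, preset):
        for seed in range(10):
            cell, _ = make_cell(preset, seed)
            assert cell.rm_gohm >= 1.0
            assert cell.cm_pf <= 35.0
            assert cell.gna_max_ns > 0

    def test_same_seed_identical(self):
        c1, g1 = make_cell("dko", 7)
        c2, g2 = make_cell("dko", 7)
        assert c1 == c2
        assert g1 == g2

    def test_dko_total_conductance_ratio_exact_per_seed(self):
        # matched seeds share base draws, so the planted ratio is exact
        for seed in range(5):
            ctrl, _ = make_cell("control", seed)
            dko, _ = make_cell("dko", seed)
            total_c = ctrl.ga_max_ns + ctrl.gk_max_ns
            total_d = dko.ga_max_ns + dko.gk_max_ns
            assert total_d / total_c == pytest.approx(0.53, rel=1e-9)


class TestStepFamily:
    def test_canonical_step_voltages_enforced(self):
        with pytest.raises(ValueError, match="step family"):
            ProtocolSpec(kind="step_iv", step_voltages_mv=(-103.0, -83.0, -63.0))
        assert step_protocol().step_voltages_mv == STEP_VOLTAGES_MV

    def test_paired_pulse_interval_enforced(self):
        with pytest.raises(ValueError, match="25 ms"):
            ProtocolSpec(kind="paired_pulse", stim_times_s=(0.02, 0.05))

    def test_minimal_stim_trial_count_warns(self):
        with pytest.warns(UserWarning, match="50-80 trials"):
            ProtocolSpec(kind="minimal_stim", n_trials=20, duration_s=0.1)


class TestClampCircuit:
    def test_probe_transient_matches_analytic_rc(self, noiseless_passive_probe):
        """Passive probe response equals the analytic RC-with-Rs solution.

        For a step dV through Rs into (Rm || Cm):
        I(t) = dV/R_tot + (dV/Rs - dV/R_tot) * exp(-t/tau),
        tau = Cm * (Rs*Rm)/(Rs+Rm).
        """
        sw, gt = noiseless_passive_probe
        rs, rm, cm = gt["rs_mohm"] * 1e-3, gt["rm_gohm"], gt["cm_pf"]
        dv = 5.0
        tau_ms = cm * rs * rm / (rs + rm)
        fs = sw.fs_hz
        i_on = int(0.1 * fs)
        t_ms = np.arange(sw.n_samples - i_on) / fs * 1e3
        i_ss = dv / (rs + rm)
        i_0 = dv / rs
        analytic = i_ss + (i_0 - i_ss) * np.exp(-t_ms / tau_ms)
        trace = sw.data[0]
        base = trace[:i_on].mean()
        seg = trace[i_on : i_on + int(0.1 * fs)] - base
        ref = analytic[: seg.size]
        assert np.max(np.abs(seg - ref)) / i_0 < 0.005

    def test_agonist_steady_state_matches_independent_integrator(self):
        """Bath-agonist response agrees with scipy's ODE solver within 2%."""
        cell, gt = make_cell("control", 3)
        cell = replace(cell, noise_sd_pa=0.0)
        proto = bath_protocol(duration_s=140.0)
        sw = simulate_voltage_clamp(cell, proto, 1)

        gs = 1e3 / cell.rs_mohm
        gl = cell.g_leak_ns
        onset = 20.0

        def rhs(t, y):
            vm = y[0]
            w = 1.0 - math.exp(-max(t - onset, 0.0) / cell.tau_wash_on_s) if t >= onset else 0.0
            i_ion = gl * (vm - cell.e_leak_mv) + (cell.ga_max_ns + cell.gk_max_ns) * w * vm
            return [(gs * (-63.0 - vm) - i_ion) / cell.cm_pf * 1e-3]  # per ms -> per s scale

        # time unit: seconds; conductances nS, Cm pF -> tau in ms, so scale 1e3
        def rhs_s(t, y):
            return [rhs(t, y)[0] * 1e3]

        sol = solve_ivp(rhs_s, (0.0, 110.0), [-63.0], rtol=1e-9, atol=1e-9, dense_output=True)
        vm_end = sol.y[0, -1]
        i_ref = gs * (-63.0 - vm_end)
        fs = sw.fs_hz
        i_sim = sw.data[0][int(109.0 * fs) : int(110.0 * fs)].mean()
        assert i_sim == pytest.approx(i_ref, rel=0.02)
        # Rs-corrected steady amplitude ~ (gA+gK) * 63 mV
        expected = -(cell.ga_max_ns + cell.gk_max_ns) * 63.0
        corrected = i_sim * (-63.0) / vm_end
        assert corrected == pytest.approx(expected, rel=0.02)

    def test_rr_ground_truth_count_within_poisson_band(self):
        """~2 Hz plateau for 360 s: the planted count sits in the 99% band."""
        cell, _ = make_cell("control", 11)
        proto = rr_protocol(duration_s=360.0, onset_s=0.0)
        sw = simulate_voltage_clamp(cell, proto, 4, rr_rise_tau_s=1e-6)
        n = len(sw.ground_truth["event_times_s"])
        lam = 2.0 * 360.0
        band = 2.576 * math.sqrt(lam)
        assert lam - band < n < lam + band

    def test_determinism_byte_identical(self):
        cell, _ = make_cell("control", 2)
        a = simulate_voltage_clamp(cell, probe_protocol(n_repeats=3), 9)
        b = simulate_voltage_clamp(cell, probe_protocol(n_repeats=3), 9)
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.command, b.command)

    def test_unstable_integration_raises(self):
        cell, _ = make_cell("control", 1)
        # a non-physical negative leak resistance makes the circuit diverge
        bad = replace(cell, rm_gohm=-0.005, noise_sd_pa=0.0)
        with pytest.raises(SimulationError):
            simulate_voltage_clamp(bad, probe_protocol(n_repeats=1), 1)


class TestCohortGenerators:
    def test_histology_planted_ol_ratio(self):
        tab, gt = simulate_histology_counts("dko", age="P14", seed=0)
        assert gt["planted_ol_ratio"] == pytest.approx(0.73)
        # large-n density estimate converges on the planted control density
        big, gt2 = simulate_histology_counts(
            "control", n_litters=12, controls_per_litter=4, mutants_per_litter=0, seed=1
        )
        cc1 = big[big.marker == "CC1"]
        d = cc1["count"].sum() / cc1["area_mm2"].sum()
        assert d == pytest.approx(gt2["ol_density_control"], rel=0.03)

    def test_histology_needs_multiple_litters(self):
        with pytest.raises(ValueError, match="litters"):
            simulate_histology_counts("dko", n_litters=1, seed=0)

    def test_caspase_planted_factor(self):
        tab, gt = simulate_caspase_cohort("dko", seed=0)
        assert gt["caspase_factor"] == pytest.approx(1.194)
        assert gt["control_fraction"] == pytest.approx(0.227)
        tab_t, gt_t = simulate_caspase_cohort("tko", seed=0)
        assert gt_t["control_fraction"] == pytest.approx(0.248)
        assert set(tab.columns) == {"litter_id", "animal_id", "genotype", "fraction"}

    def test_fiber_circumference_is_pi_d(self):
        fib, cnt, inter, gt = simulate_fiber_geometry(
            "control",
            n_animals=1,
            fibers_per_animal=5,
            axon_diameter_um=(0.8, 0.0),
            g_ratio=(0.8, 0.0),
            seed=0,
        )
        assert fib["c_axon_um"].to_numpy() == pytest.approx(np.pi * 0.8, abs=1e-9)
        assert fib["c_fiber_um"].to_numpy() == pytest.approx(np.pi * 1.0, abs=1e-9)

    def test_fiber_g_ratio_support_validated(self):
        with pytest.raises(ValueError, match="g-ratio"):
            simulate_fiber_geometry("control", g_ratio=(1.2, 0.01), seed=0)

    def test_dko_scales_only_figure_density(self):
        _, cnt_c, _, gt_c = simulate_fiber_geometry("control", seed=5)
        _, cnt_d, _, gt_d = simulate_fiber_geometry("dko", seed=5)
        assert gt_d["figure_density_per_um2"] / gt_c["figure_density_per_um2"] == pytest.approx(0.80)
        assert gt_d["g_ratio_mean"] == gt_c["g_ratio_mean"]

    def test_random_walk_has_exact_arc_length(self):
        rng = np.random.default_rng(0)
        pts = random_walk_internode(rng, 85.0)
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        assert seg.sum() == pytest.approx(85.0, abs=1e-9)
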