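"""End-to-end cohort pipelines tying the generator to the analysis chain.

These are the study-level workflows: simulate a cohort of OPs per genotype
preset, pass each cell through the passive fit and QC, then measure the
quantity of interest (Rs-corrected kainate current density, antagonist
block, or secretagogue-evoked EPSC frequency).  They return tidy per-cell
tables that the group statistics operate on, and they are what the
acceptance script runs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .events import detect_epscs, frequency_timecourse
from .passive import fit_passive, qc_cell
from .pharm import agonist_response, block_fraction
from .sweeps import SweepSet
from .synth import (
    DrugEvent,
    bath_protocol,
    make_cell,
    probe_protocol,
    rr_protocol,
    simulate_voltage_clamp,
)

__all__ = [
    "kainate_density_cohort",
    "antagonist_block_cohort",
    "rr_frequency_cohort",
]

_SMOOTH_LAST_S = 20.0


def _characterize(cell, rng):
    """Probe protocol -> passive fit (the entry point of every pipeline)."""
    probe = probe_protocol(n_repeats=10)
    sw = simulate_voltage_clamp(cell, probe, rng)
    return fit_passive(sw)


def kainate_density_cohort(
    preset: str,
    n_cells: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Rs-corrected kainate-evoked current density for a cohort.

    Per cell: passive fit from the 5 mV probe, OP QC (all cells are
    included irrespective of series resistance, as for this measurement),
    then 100 uM kainate bath application at -63 mV and
    :func:`~opclamp.pharm.agonist_response` with the fitted Rs and Cm.

    Returns per-cell rows: genotype, qc_pass, density (pA/pF, magnitude),
    fitted passive properties and the planted ground truth density.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_cells):
        cell, gt = make_cell(preset, rng)
        props = _characterize(cell, rng)
        qc = qc_cell(props, ignore_rs_rules=True)
        sw = simulate_voltage_clamp(cell, bath_protocol(), rng)
        resp = agonist_response(sw, rs_mohm=props.rs_mohm, cm_pf=props.cm_pf)
        rows.append(
            {
                "cell": f"{preset}_{i}",
                "genotype": preset,
                "qc_pass": qc.passed,
                "quantifiable": resp.quantifiable,
                "density_pa_per_pf": abs(resp.density_pa_per_pf),
                "delta_i_pa": resp.delta_i_pa,
                "i_corr_pa": resp.i_corr_pa,
                "rm_gohm": props.rm_gohm,
                "cm_pf": props.cm_pf,
                "rs_mohm": props.rs_mohm,
                "true_density_pa_per_pf": gt["kainate_density_pa_per_pf"],
            }
        )
    return pd.DataFrame(rows)


def antagonist_block_cohort(
    preset: str,
    n_cells: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Percent block of the kainate-evoked current by the AMPAR antagonist.

    Kainate is applied alone, then GYKI is co-applied; the block fraction
    compares the pre-antagonist peak with the response at the end of the
    antagonist epoch (steady block).
    """
    rng = np.random.default_rng(seed)
    proto = bath_protocol(
        drugs=(
            DrugEvent("kainate", 100.0, 20.0, 230.0),
            DrugEvent("GYKI", 50.0, 110.0, 230.0),
        ),
        duration_s=235.0,
    )
    rows = []
    for i in range(n_cells):
        cell, gt = make_cell(preset, rng)
        props = _characterize(cell, rng)
        qc = qc_cell(props, ignore_rs_rules=True)
        sw = simulate_voltage_clamp(cell, proto, rng)
        pre, during = _pre_and_during_antagonist(sw)
        rows.append(
            {
                "cell": f"{preset}_{i}",
                "genotype": preset,
                "qc_pass": qc.passed,
                "block_pct": block_fraction(pre, during),
                "true_ampar_fraction": gt["ampar_fraction"],
            }
        )
    return pd.DataFrame(rows)


def _pre_and_during_antagonist(sw: SweepSet) -> tuple[float, float]:
    from scipy.ndimage import uniform_filter1d

    drugs = {d["drug"].lower(): d for d in sw.meta["drugs"]}
    ag, ant = drugs["kainate"], drugs["gyki"]
    fs = sw.fs_hz
    smooth = uniform_filter1d(sw.data.mean(axis=0), max(1, int(1.0 * fs)))
    i_ag = int(ag["onset_s"] * fs)
    baseline = float(np.mean(smooth[max(0, i_ag - int(15 * fs)) : max(1, i_ag - int(1 * fs))]))
    i_ant = int(ant["onset_s"] * fs)
    seg_pre = smooth[i_ag:i_ant]
    pre = float(seg_pre[np.argmax(np.abs(seg_pre - baseline))] - baseline)
    i_end = min(sw.n_samples, int(ant["offset_s"] * fs))
    seg_ant = smooth[i_end - int(_SMOOTH_LAST_S * fs) : i_end]
    during = float(np.mean(seg_ant) - baseline)
    return pre, during


def rr_frequency_cohort(
    preset: str,
    n_cells: int = 15,
    seed: int = 0,
    duration_s: float = 370.0,
    onset_s: float = 10.0,
) -> pd.DataFrame:
    """Secretagogue-evoked EPSC frequency via the full detection chain.

    Per cell: a six-minute Ruthenium Red recording at -83 mV, EPSC
    detection with the stated criteria, and the mean frequency over
    minutes 3-6 after drug onset.  Also reports the mean amplitude of
    accepted events inside the window (amplitude is the genotype-invariant
    quantity) and the ground-truth event count for audit.
    """
    rng = np.random.default_rng(seed)
    proto = rr_protocol(duration_s=duration_s, onset_s=onset_s)
    rows = []
    for i in range(n_cells):
        cell, _ = make_cell(preset, rng)
        sw = simulate_voltage_clamp(cell, proto, rng)
        events = detect_epscs(sw)
        _, window_hz = frequency_timecourse(
            events, drug_onset_s=onset_s, recording_end_s=duration_s
        )
        t = events.times
        in_win = (t >= onset_s + 180.0) & (t < onset_s + 360.0)
        # quantal amplitude summary: well-isolated events only, summarized
        # by the per-cell median — coincident events that merge into one
        # detected excursion would otherwise inflate a mean
        gaps = np.diff(t, prepend=-np.inf)
        isolated = (gaps > 0.02) & (np.append(np.diff(t), np.inf) > 0.02)
        amps = events.amplitudes[in_win & isolated]
        rows.append(
            {
                "cell": f"{preset}_{i}",
                "genotype": preset,
                "window_freq_hz": window_hz,
                "mean_amp_pa": float(np.median(amps)) if amps.size else np.nan,
                "n_detected": int(in_win.sum()),
                "n_true_events": int(len(sw.ground_truth["event_times_s"])),
                "noise_sd_pa": events.noise_sd_pa,
            }
        )
    return pd.DataFrame(rows)
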