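"""Forward simulation of whole-cell voltage clamp through a series resistance.

The recorded circuit is a single compartment clamped through an access
resistance Rs: the membrane potential obeys

    Cm dVm/dt = (Vcmd - Vm)/Rs - I_ion(Vm, t)

and the recorded current is (Vcmd - Vm)/Rs.  This reproduces the
capacitive transient, the Rs voltage error on large currents and the
low-pass filtering of fast synaptic events that the analysis modules must
cope with.  I_ion comprises an ohmic leak, m^3 h sodium channels,
bath-agonist-gated AMPAR/KAR conductances with first-order wash-in/out and
biexponential synaptic conductance events (reversal 0 mV).

Integration uses an exponential-Euler update on Vm (exact for a linear
cell over each substep of piecewise-constant command voltage) with
substeps chosen to resolve the clamp time constant Cm*(Rs||Rm) and the
sodium activation kinetics.  A runaway or non-finite state raises
:class:`~opclamp.sweeps.SimulationError` rather than returning garbage.
"""

from __future__ import annotations

import math
from typing import Any

import numpy as np
from numba import njit

from ..sweeps import SimulationError, SweepSet
from .cells import CellModelParams
from .presets import GenotypePreset, get_preset
from .protocols import ProtocolSpec

__all__ = [
    "simulate_voltage_clamp",
    "RR_PLATEAU_HZ",
    "RR_BASELINE_HZ",
    "RR_RISE_TAU_S",
    "EPSC_RISE_MS",
    "EPSC_DECAY_MS",
]

#: Control plateau rate of Ruthenium-Red-evoked EPSCs (Hz).  The absolute
#: rate is a generator scale choice; genotype presets scale it.
RR_PLATEAU_HZ = 2.0
#: Spontaneous EPSC rate before the secretagogue ("very low frequency").
RR_BASELINE_HZ = 0.02
#: First-order rise of the RR-evoked rate; the rate is essentially at
#: plateau by 3 min after drug onset, matching the analysis window.
RR_RISE_TAU_S = 60.0

EPSC_RISE_MS = 0.3
EPSC_DECAY_MS = 3.0

_HUGE = 1e30


@njit(cache=True)
def _integrate(
    vcmd,
    dt_ms,
    nsub,
    cm,
    gs,
    gl,
    el,
    gna,
    ena,
    m_half,
    m_slope,
    tau_m,
    h_half,
    h_slope,
    tau_h,
    ga,
    gk,
    rect,
    vh,
    vk,
    ag_on,
    ag_off,
    tau_on_s,
    tau_off_s,
    ag0,
    ant_on,
    ant_off,
    ant0,
    ev_idx,
    ev_g,
    tau_r_ms,
    tau_d_ms,
    vm0,
):
    n = vcmd.size
    out = np.empty(n)
    dt_s = dt_ms * 1e-3
    a_r = math.exp(-dt_ms / tau_r_ms)
    a_d = math.exp(-dt_ms / tau_d_ms)
    a_on = 1.0 - math.exp(-dt_s / tau_on_s)
    a_off = 1.0 - math.exp(-dt_s / tau_off_s)
    vm = vm0
    m = 1.0 / (1.0 + math.exp(-(vm - m_half) / m_slope))
    h = 1.0 / (1.0 + math.exp((vm - h_half) / h_slope))
    wag = ag0
    want = ant0
    xr = 0.0
    xd = 0.0
    k = 0
    n_ev = ev_idx.size
    for i in range(n):
        vc = vcmd[i]
        # instantaneous recorded current at the start of the sample period
        out[i] = gs * (vc - vm)
        base = i * nsub
        for j in range(nsub):
            idx = base + j
            while k < n_ev and ev_idx[k] == idx:
                xr += ev_g[k]
                xd += ev_g[k]
                k += 1
            t_s = idx * dt_s
            # bath drug gates: first-order wash-in toward 1, wash-out toward 0
            if ag_on <= t_s < ag_off:
                wag += (1.0 - wag) * a_on
            else:
                wag -= wag * a_off
            if ant_on <= t_s < ant_off:
                want += (1.0 - want) * a_on
            else:
                want -= want * a_off
            # conductances at the current Vm
            g_na = gna * m * m * m * h
            if rect:
                f_open = 1.0 / (1.0 + math.exp((vm - vh) / vk))
            else:
                f_open = 1.0
            g_ampar = ga * wag * (1.0 - want) * f_open
            g_kar = gk * wag
            g_syn = xd - xr
            g_tot = gs + gl + g_na + g_ampar + g_kar + g_syn
            num = gs * vc + gl * el + g_na * ena  # glutamatergic terms revert to 0 mV
            vss = num / g_tot
            vm = vss + (vm - vss) * math.exp(-dt_ms * g_tot / cm)
            if not (-500.0 < vm < 500.0):
                return out, _HUGE
            # gating relaxation
            m_inf = 1.0 / (1.0 + math.exp(-(vm - m_half) / m_slope))
            h_inf = 1.0 / (1.0 + math.exp((vm - h_half) / h_slope))
            m += (m_inf - m) * (1.0 - math.exp(-dt_ms / tau_m))
            h += (h_inf - h) * (1.0 - math.exp(-dt_ms / tau_h))
            xr *= a_r
            xd *= a_d
    return out, vm


def _epsc_peak_norm(tau_r_ms: float, tau_d_ms: float) -> float:
    tp = tau_r_ms * tau_d_ms / (tau_d_ms - tau_r_ms) * math.log(tau_d_ms / tau_r_ms)
    return math.exp(-tp / tau_d_ms) - math.exp(-tp / tau_r_ms)


def _clamp_attenuation(cell: CellModelParams, tau_r_ms: float, tau_d_ms: float) -> float:
    """Peak attenuation of a biexponential synaptic current by the clamp RC.

    The recorded current follows the synaptic current through a first-order
    filter with time constant Cm * (Rs || Rm); planted event amplitudes are
    divided by this factor so the *recorded* peak matches the planted value.
    """
    r_par = (cell.rs_mohm * 1e-3 * cell.rm_gohm) / (cell.rs_mohm * 1e-3 + cell.rm_gohm)
    tau_c = cell.cm_pf * r_par  # ms
    dt = 0.005
    t = np.arange(0.0, 10.0 * tau_d_ms, dt)
    g = np.exp(-t / tau_d_ms) - np.exp(-t / tau_r_ms)
    g /= g.max()
    y = 0.0
    a = math.exp(-dt / tau_c)
    peak = 0.0
    for gi in g:
        y = gi + (y - gi) * a
        if y > peak:
            peak = y
    return peak


def _rr_event_times(
    rng: np.random.Generator,
    duration_s: float,
    onset_s: float,
    baseline_hz: float,
    plateau_hz: float,
    rise_tau_s: float,
) -> np.ndarray:
    """Inhomogeneous-Poisson event times via thinning."""
    r_max = max(baseline_hz, plateau_hz)
    n_max = rng.poisson(r_max * duration_s)
    cand = np.sort(rng.uniform(0.0, duration_s, n_max))
    rate = np.where(
        cand < onset_s,
        baseline_hz,
        baseline_hz
        + (plateau_hz - baseline_hz) * (1.0 - np.exp(-(cand - onset_s) / rise_tau_s)),
    )
    keep = rng.uniform(0.0, 1.0, n_max) < rate / r_max
    return cand[keep]


def simulate_voltage_clamp(
    cell: CellModelParams,
    protocol: ProtocolSpec,
    seed: int | np.random.Generator,
    preset: str | GenotypePreset | None = None,
    rr_plateau_hz: float = RR_PLATEAU_HZ,
    rr_rise_tau_s: float = RR_RISE_TAU_S,
    minimal_stim_p: float = 0.5,
    minimal_stim_amp_pa: tuple[float, float] = (15.0, 3.0),
    paired_pulse_amp_pa: float = 60.0,
    paired_pulse_second_rel: float = 0.9,
) -> SweepSet:
    """Simulate one protocol on one cell, returning sweeps plus ground truth.

    ``preset`` supplies the genotype-level synaptic parameters (event rate
    scaling and amplitude distribution) for the synaptic scenarios; when
    omitted it is looked up from ``cell.meta['genotype']``.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    fs = protocol.fs_hz
    dt_sample_ms = 1000.0 / fs
    dt_target_ms = 0.02 if protocol.kind in ("step_iv", "minimal_stim", "paired_pulse") else 0.05
    nsub = max(1, int(math.ceil(dt_sample_ms / dt_target_ms)))
    dt_ms = dt_sample_ms / nsub

    cmd = protocol.command_waveforms()
    n_sweeps, n_samples = cmd.shape
    gs = 1000.0 / cell.rs_mohm  # nS
    rect = cell.rectifying and protocol.spermine

    # bath drug schedule
    ag_on, ag_off, ag0 = math.inf, math.inf, 0.0
    ant_on, ant_off, ant0 = math.inf, math.inf, 0.0
    for ev in protocol.drugs:
        if ev.drug.lower() in ("kainate", "ampa", "rr"):
            ag_on, ag_off = ev.onset_s, ev.offset_s
        elif ev.drug.lower() in ("gyki", "gyki52466", "gyki-52466", "nbqx"):
            ant_on, ant_off = ev.onset_s, ev.offset_s
    if protocol.drug_steady:
        ag_on, ag_off, ag0 = 0.0, math.inf, 1.0
    # Ruthenium Red drives release, it is not a postsynaptic agonist
    rr_like = protocol.kind == "rr_epsc"
    ga_ns = cell.ga_max_ns if (not rr_like and ag_on < math.inf) else 0.0
    gk_ns = cell.gk_max_ns if (not rr_like and ag_on < math.inf) else 0.0

    peak_norm = _epsc_peak_norm(EPSC_RISE_MS, EPSC_DECAY_MS)
    drive_mv = abs(protocol.holding_mv - cell.e_glu_mv)
    if protocol.kind in ("rr_epsc", "minimal_stim", "paired_pulse"):
        # plant *recorded* peak amplitudes: undo the clamp RC attenuation
        drive_mv *= _clamp_attenuation(cell, EPSC_RISE_MS, EPSC_DECAY_MS)

    # initial Vm: passive steady state at the holding potential
    gl = cell.g_leak_ns
    vm0 = (gs * protocol.holding_mv + gl * cell.e_leak_mv) / (gs + gl)

    preset_obj: GenotypePreset | None = None
    if protocol.kind in ("rr_epsc", "minimal_stim"):
        name = preset if preset is not None else cell.meta.get("genotype", "control")
        preset_obj = get_preset(name)

    data = np.empty((n_sweeps, n_samples))
    gt: dict[str, Any] = {"protocol": protocol.kind, "seed_used": True}
    all_times: list[np.ndarray] = []
    all_amps: list[np.ndarray] = []
    successes: list[bool] = []

    for s in range(n_sweeps):
        ev_idx = np.empty(0, dtype=np.int64)
        ev_g = np.empty(0)
        if protocol.kind == "rr_epsc":
            rate = rr_plateau_hz * preset_obj.synapse_rate_rel
            times = _rr_event_times(
                rng, protocol.duration_s, ag_on, RR_BASELINE_HZ, rate, rr_rise_tau_s
            )
            amps = np.maximum(
                rng.normal(
                    preset_obj.epsc_amplitude_mean_pa,
                    preset_obj.epsc_amplitude_sd_pa,
                    times.size,
                ),
                2.0,
            )
            ev_idx = np.round(times * fs * nsub).astype(np.int64)
            ev_g = amps / drive_mv / peak_norm
            all_times.append(times)
            all_amps.append(amps)
            gt["rr_rate_plateau_hz"] = rate
        elif protocol.kind == "minimal_stim":
            ok = rng.uniform() < minimal_stim_p
            successes.append(bool(ok))
            amp = max(rng.normal(*minimal_stim_amp_pa), 1.0) if ok else 0.0
            if ok:
                times = np.array(protocol.stim_times_s)
                ev_idx = np.round(times * fs * nsub).astype(np.int64)
                ev_g = np.full(times.size, amp / drive_mv / peak_norm)
                all_times.append(times)
                all_amps.append(np.array([amp]))
        elif protocol.kind == "paired_pulse":
            amps = np.array(
                [paired_pulse_amp_pa, paired_pulse_amp_pa * paired_pulse_second_rel]
            )
            times = np.asarray(protocol.stim_times_s)
            ev_idx = np.round(times * fs * nsub).astype(np.int64)
            ev_g = amps / drive_mv / peak_norm
            all_times.append(times)
            all_amps.append(amps)

        trace, vm_end = _integrate(
            cmd[s],
            dt_ms,
            nsub,
            cell.cm_pf,
            gs,
            gl,
            cell.e_leak_mv,
            cell.gna_max_ns,
            cell.e_na_mv,
            cell.na_m_half_mv,
            cell.na_m_slope_mv,
            cell.na_tau_m_ms,
            cell.na_h_half_mv,
            cell.na_h_slope_mv,
            cell.na_tau_h_ms,
            ga_ns,
            gk_ns,
            rect,
            cell.rect_vh_mv,
            cell.rect_k_mv,
            ag_on,
            ag_off,
            cell.tau_wash_on_s,
            cell.tau_wash_off_s,
            ag0,
            ant_on,
            ant_off,
            ant0,
            ev_idx,
            ev_g,
            EPSC_RISE_MS,
            EPSC_DECAY_MS,
            vm0,
        )
        if vm_end >= _HUGE or not np.all(np.isfinite(trace)):
            raise SimulationError(
                "voltage-clamp integration diverged (membrane potential out of "
                "range); reduce the integration step or check parameters"
            )
        if cell.noise_sd_pa > 0:
            trace = trace + rng.normal(0.0, cell.noise_sd_pa, n_samples)
        data[s] = trace

    if protocol.kind in ("rr_epsc", "paired_pulse"):
        gt["event_times_s"] = all_times[0] if n_sweeps == 1 else all_times
        gt["event_amps_pa"] = all_amps[0] if n_sweeps == 1 else all_amps
    if protocol.kind == "minimal_stim":
        gt["successes"] = np.array(successes)
        gt["success_amps_pa"] = (
            np.concatenate(all_amps) if all_amps else np.empty(0)
        )
        gt["p_success"] = minimal_stim_p
        gt["unitary_amp_pa"] = minimal_stim_amp_pa[0]
    if protocol.kind == "paired_pulse":
        gt["ppr"] = paired_pulse_second_rel
    gt.update(
        rm_gohm=cell.rm_gohm,
        cm_pf=cell.cm_pf,
        rs_mohm=cell.rs_mohm,
        ga_max_ns=cell.ga_max_ns,
        gk_max_ns=cell.gk_max_ns,
    )

    meta = {
        "kind": protocol.kind,
        "holding_mv": protocol.holding_mv,
        "rs_mohm": cell.rs_mohm,
        "cm_pf": cell.cm_pf,
        "genotype": cell.meta.get("genotype"),
        "spermine": protocol.spermine,
        "drugs": [
            {"drug": d.drug, "conc_um": d.conc_um, "onset_s": d.onset_s, "offset_s": d.offset_s}
            for d in protocol.drugs
        ],
        "stim_times_s": list(protocol.stim_times_s),
        "noise_sd_pa": cell.noise_sd_pa,
    }
    return SweepSet(data=data, command=cmd, fs_hz=fs, meta=meta, ground_truth=gt)
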