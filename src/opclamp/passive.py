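"""Passive membrane properties from the 5 mV probe transient, plus cell QC.

The transient current elicited by a small voltage step in a single
compartment clamped through Rs is a single exponential,

    I(t) = I_ss + (I_0 - I_ss) * exp(-t / tau),

measured relative to the pre-step baseline.  From the fit:
Rs = dV / I_0, R_total = dV / I_ss, Rm = R_total - Rs and
Cm = tau / (Rs * Rm / (Rs + Rm)).  Repeated probes are averaged before
fitting.  The fit window starts 0.2 ms after the step to skip clamp
settling, and I_0 is the fit's extrapolation to step onset rather than the
raw peak sample (robust to filtering).

Cell inclusion rules for OPs: Rm >= 1 GOhm and Cm <= 35 pF; recordings are
excluded when Rs exceeds 30 MOhm or changes by more than 50% from its
first value, unless the analysis explicitly includes all cells
irrespective of series resistance (``ignore_rs_rules``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .sweeps import SweepSet

__all__ = ["PassiveProps", "PassiveFitError", "QCDecision", "fit_passive", "qc_cell"]

RM_MIN_GOHM = 1.0
CM_MAX_PF = 35.0
RS_MAX_MOHM = 30.0
RS_MAX_REL_CHANGE = 0.5
FIT_START_MS = 0.2


class PassiveFitError(RuntimeError):
    """Probe transient cannot be resolved into (Rs, Rm, Cm)."""


@dataclass
class PassiveProps:
    rm_gohm: float
    cm_pf: float
    rs_mohm: float
    tau_ms: float
    fit_rms_pa: float
    qc_pass: bool = True
    qc_reasons: list[str] = field(default_factory=list)


@dataclass
class QCDecision:
    passed: bool
    reasons: list[str]


def _exp_model(t, i_ss, i_0, tau):
    return i_ss + (i_0 - i_ss) * np.exp(-t / tau)


def fit_passive(sweeps: SweepSet, baseline_s: float = 0.05) -> PassiveProps:
    """Fit the averaged probe transient and resolve Rm, Cm, Rs.

    ``sweeps`` must contain a voltage-step probe (detected from the
    command waveform) with at least ``baseline_s`` of pre-step baseline.

    Raises :class:`PassiveFitError` for degenerate transients (no
    resolvable peak, i.e. I_0 ~ I_ss), fit non-convergence or negative
    resolved resistances.
    """
    cmd = sweeps.command[0]
    dcmd = np.flatnonzero(np.diff(cmd) != 0)
    if dcmd.size == 0:
        raise PassiveFitError("no voltage step found in the command waveform")
    i_on = int(dcmd[0]) + 1
    dv = float(cmd[i_on] - cmd[i_on - 1])
    if i_on < int(baseline_s * sweeps.fs_hz):
        raise PassiveFitError(f"need >= {baseline_s * 1e3:.0f} ms of baseline before the step")
    # end of the step (or end of trace)
    later = dcmd[dcmd > i_on - 1 + 1]
    i_off = int(later[0]) + 1 if later.size else sweeps.n_samples

    trace = sweeps.data.mean(axis=0)
    baseline = float(np.mean(trace[i_on - int(baseline_s * sweeps.fs_hz) : i_on]))
    seg = trace[i_on:i_off] - baseline
    t_ms = np.arange(seg.size) / sweeps.fs_hz * 1e3
    start = int(np.ceil(FIT_START_MS / 1e3 * sweeps.fs_hz))
    if seg.size - start < 10:
        raise PassiveFitError("probe step too short to fit")

    i_ss0 = float(np.mean(seg[int(0.8 * seg.size) :]))
    peak0 = float(seg[np.argmax(np.abs(seg[: max(start * 5, 10)]))])
    if abs(peak0 - i_ss0) < 1e-12 or abs(peak0) < 1e-12:
        raise PassiveFitError("zero transient: cannot resolve Rs (I_0 == I_ss)")
    # crude tau guess: time to decay to 1/e of the excursion
    dec = np.abs(seg - i_ss0) < abs(peak0 - i_ss0) / np.e
    tau0 = t_ms[np.argmax(dec)] if dec.any() else t_ms[-1] / 5
    tau0 = max(tau0, 2 * t_ms[1])
    try:
        popt, _ = curve_fit(
            _exp_model,
            t_ms[start:],
            seg[start:],
            p0=(i_ss0, peak0, tau0),
            maxfev=10_000,
        )
    except RuntimeError as exc:
        raise PassiveFitError(f"exponential fit did not converge: {exc}") from exc
    i_ss, i_0, tau = map(float, popt)
    if tau <= 0:
        raise PassiveFitError(f"non-physical fitted time constant {tau:.3g} ms")
    rms = float(np.sqrt(np.mean((seg[start:] - _exp_model(t_ms[start:], *popt)) ** 2)))

    if abs(i_0) < 1e-12 or abs(i_ss) < 1e-12 or abs(i_0 - i_ss) < 1e-9:
        raise PassiveFitError("zero transient: cannot resolve Rs (I_0 == I_ss)")
    rs_gohm = dv / i_0  # mV / pA = GOhm
    r_total = dv / i_ss
    rm_gohm = r_total - rs_gohm
    if rs_gohm <= 0 or rm_gohm <= 0:
        raise PassiveFitError(
            f"negative resolved resistance (Rs={rs_gohm:.3g} GOhm, Rm={rm_gohm:.3g} GOhm)"
        )
    cm_pf = tau / (rs_gohm * rm_gohm / (rs_gohm + rm_gohm))
    return PassiveProps(
        rm_gohm=rm_gohm,
        cm_pf=cm_pf,
        rs_mohm=rs_gohm * 1e3,
        tau_ms=tau,
        fit_rms_pa=rms,
    )


def qc_cell(
    props: Sequence[PassiveProps] | PassiveProps,
    ignore_rs_rules: bool = False,
) -> QCDecision:
    """Apply the OP inclusion / recording-stability rules to a cell.

    ``props`` is the time course of passive fits over the recording (one
    entry is enough).  Fails when Rm < 1 GOhm or Cm > 35 pF (not an OP),
    when Rs > 30 MOhm at any point, or when Rs changes by more than 50%
    relative to its first value.  ``ignore_rs_rules=True`` bypasses the two
    Rs rules for analyses that include all cells irrespective of Rs.
    """
    if isinstance(props, PassiveProps):
        props = [props]
    if len(props) == 0:
        raise ValueError("qc_cell needs at least one PassiveProps measurement")
    reasons: list[str] = []
    rm = min(p.rm_gohm for p in props)
    cm = max(p.cm_pf for p in props)
    if rm < RM_MIN_GOHM:
        reasons.append(f"not OP: Rm<1GOhm (min {rm:.2f} GOhm)")
    if cm > CM_MAX_PF:
        reasons.append(f"not OP: Cm>35pF (max {cm:.1f} pF)")
    if not ignore_rs_rules:
        rs = np.array([p.rs_mohm for p in props])
        if np.any(rs > RS_MAX_MOHM):
            reasons.append(f"Rs>30MOhm (max {rs.max():.1f} MOhm)")
        rel = np.abs(rs - rs[0]) / rs[0]
        if np.any(rel > RS_MAX_REL_CHANGE):
            reasons.append(f"Rs changed by >50% ({100 * rel.max():.0f}%)")
    return QCDecision(passed=not reasons, reasons=reasons)
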