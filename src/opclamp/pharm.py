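"""Bath-agonist pharmacology: evoked current, Rs correction, I-V and block.

The peak kainate-evoked current is measured on a 1 s moving-average
smoothed holding current (bath responses are slow).  Because the recording
is made through a series resistance without compensation, the actual
membrane potential during a response differs from the command:
Vm = Vcmd - I_tot * Rs.  With a 0 mV reversal potential for the
agonist-gated current, the corrected amplitude is

    I_corr = dI_meas * (Vcmd - E_rev) / (Vm_during - E_rev)

using the total current flowing at the response peak.  Current density is
I_corr normalized to membrane capacitance (proportional to cell surface
area).

The rectification index of an I-V family is RI = I(+17 mV) / I(-63 mV) of
the drug-evoked (drug minus control) step currents; an ohmic conductance
reversing at 0 mV gives RI = 17/63, and polyamine-blocked GluA2-lacking
AMPARs give RI near 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .sweeps import SweepSet

__all__ = ["AgonistResponse", "IVCurve", "agonist_response", "build_iv_and_ri", "block_fraction"]

E_REV_MV = 0.0
SMOOTH_S = 1.0
STEADY_STATE_S = 0.05  # last 50 ms of each 200 ms step
MIN_DRIVING_FORCE_MV = 5.0


@dataclass
class AgonistResponse:
    delta_i_pa: float  # measured peak deflection (signed; inward negative)
    i_corr_pa: float  # Rs-corrected amplitude
    density_pa_per_pf: float  # I_corr / Cm
    vm_during_mv: float
    peak_time_s: float
    quantifiable: bool = True


@dataclass
class IVCurve:
    voltages_mv: np.ndarray
    current_pa: np.ndarray  # drug-evoked (drug minus control) steady-state current
    ri: float  # I(+17) / I(-63)


def agonist_response(
    sweeps: SweepSet,
    rs_mohm: float | None = None,
    cm_pf: float | None = None,
    drug: str = "kainate",
) -> AgonistResponse:
    """Measure and Rs-correct the bath-agonist-evoked holding current.

    ``rs_mohm`` / ``cm_pf`` default to the values in ``sweeps.meta`` (use
    the passive-fit estimates for real analyses).  The drug window is read
    from the recorded schedule.  Raises ``ValueError`` if the drug window
    lies outside the recording; returns ``quantifiable=False`` when the
    membrane potential during the response approaches the reversal
    potential (driving force too small to correct).
    """
    rs = sweeps.meta.get("rs_mohm") if rs_mohm is None else rs_mohm
    cm = sweeps.meta.get("cm_pf") if cm_pf is None else cm_pf
    if rs is None or cm is None or cm <= 0:
        raise ValueError("series resistance and capacitance are required")
    sched = [d for d in sweeps.meta.get("drugs", []) if d["drug"].lower() == drug.lower()]
    if not sched:
        raise ValueError(f"no {drug!r} application in the recorded schedule")
    onset, offset = sched[0]["onset_s"], sched[0]["offset_s"]
    if onset >= sweeps.duration:
        raise ValueError("drug window lies outside the recording")
    vcmd = float(sweeps.command[0, 0])

    trace = sweeps.data.mean(axis=0)
    w = max(1, int(SMOOTH_S * sweeps.fs_hz))
    smooth = uniform_filter1d(trace, w)
    fs = sweeps.fs_hz
    i_on = int(onset * fs)
    base = smooth[max(0, i_on - int(30 * fs)) : max(1, i_on - int(1 * fs))]
    baseline = float(np.mean(base)) if base.size else float(smooth[0])
    i_end = min(sweeps.n_samples, int((offset + 30.0) * fs))
    seg = smooth[i_on:i_end]
    k = int(np.argmax(np.abs(seg - baseline)))
    peak_val = float(seg[k])
    delta_i = peak_val - baseline

    vm_during = vcmd - peak_val * rs / 1e3  # pA * MOhm = uV -> mV
    if abs(vm_during - E_REV_MV) < MIN_DRIVING_FORCE_MV:
        return AgonistResponse(delta_i, np.nan, np.nan, vm_during, (i_on + k) / fs, False)
    i_corr = delta_i * (vcmd - E_REV_MV) / (vm_during - E_REV_MV)
    return AgonistResponse(
        delta_i_pa=delta_i,
        i_corr_pa=i_corr,
        density_pa_per_pf=i_corr / cm,
        vm_during_mv=vm_during,
        peak_time_s=(i_on + k) / fs,
    )


def _step_steady_state(sweeps: SweepSet) -> tuple[np.ndarray, np.ndarray]:
    cmd = sweeps.command
    changes = np.flatnonzero(np.any(np.diff(cmd, axis=1) != 0, axis=0))
    if changes.size == 0:
        raise ValueError("no voltage steps found")
    i_on = int(changes[0]) + 1
    later = changes[changes >= i_on]
    i_off = int(later[0]) + 1 if later.size else sweeps.n_samples
    n_ss = int(STEADY_STATE_S * sweeps.fs_hz)
    ss = sweeps.data[:, max(i_on, i_off - n_ss) : i_off].mean(axis=1)
    return cmd[:, i_on], ss


def build_iv_and_ri(control_steps: SweepSet, drug_steps: SweepSet) -> IVCurve:
    """Drug-evoked I-V relation and rectification index from step families.

    Both sweep sets must use the identical step protocol; the drug-evoked
    current at each voltage is the steady-state (last 50 ms of the step)
    drug current minus the control current.
    """
    if control_steps.command.shape != drug_steps.command.shape or not np.allclose(
        control_steps.command, drug_steps.command
    ):
        raise ValueError("control and drug step protocols differ")
    v, ss_ctrl = _step_steady_state(control_steps)
    _, ss_drug = _step_steady_state(drug_steps)
    evoked = ss_drug - ss_ctrl
    at = {}
    for target in (17.0, -63.0):
        idx = np.flatnonzero(np.isclose(v, target))
        if idx.size == 0:
            raise ValueError(f"step family lacks the {target:+.0f} mV step needed for RI")
        at[target] = float(evoked[idx[0]])
    if at[-63.0] == 0:
        raise ValueError("zero drug-evoked current at -63 mV; RI undefined")
    # RI is a ratio of current amplitudes; the raw currents have opposite
    # signs on either side of the 0 mV reversal potential
    return IVCurve(voltages_mv=v, current_pa=evoked, ri=abs(at[17.0]) / abs(at[-63.0]))


def block_fraction(pre_pa: float, during_antagonist_pa: float) -> float:
    """Percent block: 100 * (1 - response during antagonist / response before).

    Also applicable to event frequencies.  Raises on a zero pre-drug
    response.
    """
    if pre_pa == 0:
        raise ValueError("pre-antagonist response is zero; block undefined")
    return 100.0 * (1.0 - during_antagonist_pa / pre_pa)
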