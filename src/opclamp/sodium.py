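"""Voltage-gated Na+ current isolation by linearly scaled passive subtraction.

The response to a 20 mV hyperpolarizing step (to -83 mV from -63 mV) has no
active component: it is the capacitive transient plus ohmic leak, both
proportional to the step size.  Scaling that template by dV / (-20 mV) and
subtracting it from each step response cancels the passive component
exactly for a linear cell — including the Rs distortion, which the scaled
template shares — leaving the voltage-gated current.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sweeps import SweepSet

__all__ = ["NaCurrentResult", "isolate_na_current"]

TEMPLATE_STEP_MV = -20.0
PEAK_WINDOW_MS = 10.0


@dataclass
class NaCurrentResult:
    subtracted: np.ndarray  # (n_sweeps, n_samples), pA
    step_voltages_mv: np.ndarray
    peak_ina_pa: float  # most negative subtracted excursion (depolarizing steps)
    peak_step_mv: float  # step voltage at which the peak occurred
    ina_density_pa_per_pf: float


def isolate_na_current(sweeps: SweepSet, cm_pf: float) -> NaCurrentResult:
    """Subtract the scaled passive template and measure peak I_Na.

    ``sweeps`` must be a step family that includes the 20 mV
    hyperpolarizing step; ``cm_pf`` (from the passive fit) normalizes the
    peak to a density.  Multiple hyperpolarizing repeats are averaged
    before scaling.  The peak is the most negative excursion within the
    first 10 ms of each depolarizing step.
    """
    if cm_pf <= 0:
        raise ValueError("cm_pf must be positive (run the passive fit first)")
    cmd = sweeps.command
    holding = cmd[:, 0]
    # step onset: first command change in any sweep
    changes = np.flatnonzero(np.any(np.diff(cmd, axis=1) != 0, axis=0))
    if changes.size == 0:
        raise ValueError("no voltage steps found")
    i_on = int(changes[0]) + 1
    step_v = cmd[:, i_on]
    dv = step_v - holding

    template_rows = np.flatnonzero(np.isclose(dv, TEMPLATE_STEP_MV))
    if template_rows.size == 0:
        raise ValueError("protocol lacks the 20 mV hyperpolarizing template step")

    base_n = max(1, i_on // 2)
    resp = sweeps.data - sweeps.data[:, i_on - base_n : i_on].mean(axis=1, keepdims=True)
    template = resp[template_rows].mean(axis=0)

    subtracted = resp - np.outer(dv / TEMPLATE_STEP_MV, template)

    win = slice(i_on, i_on + int(PEAK_WINDOW_MS * 1e-3 * sweeps.fs_hz))
    depol = np.flatnonzero(dv > 0)
    if depol.size == 0:
        raise ValueError("no depolarizing steps in the protocol")
    mins = subtracted[depol, win].min(axis=1)
    k = int(np.argmin(mins))
    peak = float(mins[k])
    return NaCurrentResult(
        subtracted=subtracted,
        step_voltages_mv=step_v,
        peak_ina_pa=peak,
        peak_step_mv=float(step_v[depol[k]]),
        ina_density_pa_per_pf=peak / cm_pf,
    )
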