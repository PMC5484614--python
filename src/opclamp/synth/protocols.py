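"""Voltage-clamp protocol specifications.

The protocols mirror the recording configurations used for OP
characterization in acute white-matter slices: a 5 mV probe step for
passive properties, the seven-step I-V family (-103 ... +17 mV in 20 mV
increments from -63 mV), slow bath agonist application at a fixed holding
potential, secretagogue (Ruthenium Red) EPSC recordings at -83 mV, minimal
stimulation (50-80 trials) and paired pulses 25 ms apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DrugEvent",
    "ProtocolSpec",
    "STEP_VOLTAGES_MV",
    "probe_protocol",
    "step_protocol",
    "bath_protocol",
    "rr_protocol",
    "minimal_stim_protocol",
    "paired_pulse_protocol",
]

#: The canonical step family: 20 mV increments from -103 to +17 mV.
STEP_VOLTAGES_MV = (-103.0, -83.0, -63.0, -43.0, -23.0, -3.0, 17.0)

PAIRED_PULSE_INTERVAL_S = 0.025


@dataclass(frozen=True)
class DrugEvent:
    """One bath-application epoch: drug name, concentration, on/off times (s)."""

    drug: str
    conc_um: float
    onset_s: float
    offset_s: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("drug offset must follow onset")


@dataclass(frozen=True)
class ProtocolSpec:
    """Full description of one episodic or gap-free protocol."""

    kind: str  # step_iv | agonist_bath | rr_epsc | minimal_stim | paired_pulse | passive_probe
    holding_mv: float = -63.0
    fs_hz: float = 10_000.0
    # step protocols
    step_voltages_mv: tuple[float, ...] = ()
    step_dur_s: float = 0.2
    pre_s: float = 0.1
    post_s: float = 0.1
    # passive probe
    probe_mv: float = 5.0
    n_repeats: int = 1
    # bath protocols
    duration_s: float = 0.0
    drugs: tuple[DrugEvent, ...] = ()
    spermine: bool = False  # intracellular spermine present (enables rectification)
    drug_steady: bool = False  # agonist held at full wash-in for the whole sweep
    # stimulation protocols
    stim_times_s: tuple[float, ...] = ()
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.kind == "step_iv" and self.step_voltages_mv:
            got = tuple(round(v, 6) for v in self.step_voltages_mv)
            if got != STEP_VOLTAGES_MV:
                raise ValueError(
                    f"step family must be {STEP_VOLTAGES_MV} mV, got {got}"
                )
        if self.kind == "paired_pulse" and len(self.stim_times_s) >= 2:
            ipi = self.stim_times_s[1] - self.stim_times_s[0]
            if abs(ipi - PAIRED_PULSE_INTERVAL_S) > 1e-9:
                raise ValueError("paired-pulse interval must be 25 ms")
        if self.kind == "minimal_stim" and not (50 <= self.n_trials <= 80):
            warnings.warn(
                f"minimal stimulation normally uses 50-80 trials, got {self.n_trials}",
                stacklevel=2,
            )

    @property
    def sweep_samples(self) -> int:
        if self.kind in ("step_iv", "passive_probe"):
            dur = self.pre_s + self.step_dur_s + self.post_s
        else:
            dur = self.duration_s
        return int(round(dur * self.fs_hz))

    def command_waveforms(self) -> np.ndarray:
        """Per-sweep command voltage arrays, shape ``(n_sweeps, n_samples)``."""
        n = self.sweep_samples
        if self.kind == "step_iv":
            volts = self.step_voltages_mv or STEP_VOLTAGES_MV
            cmd = np.full((len(volts), n), self.holding_mv)
            i0 = int(round(self.pre_s * self.fs_hz))
            i1 = int(round((self.pre_s + self.step_dur_s) * self.fs_hz))
            for k, v in enumerate(volts):
                cmd[k, i0:i1] = v
            return cmd
        if self.kind == "passive_probe":
            cmd = np.full((max(1, self.n_repeats), n), self.holding_mv)
            i0 = int(round(self.pre_s * self.fs_hz))
            i1 = int(round((self.pre_s + self.step_dur_s) * self.fs_hz))
            cmd[:, i0:i1] = self.holding_mv + self.probe_mv
            return cmd
        # gap-free and stimulus-locked protocols hold a constant potential
        n_sweeps = max(1, self.n_trials) if self.kind in ("minimal_stim", "paired_pulse") else 1
        return np.full((n_sweeps, n), self.holding_mv)


def probe_protocol(
    n_repeats: int = 20,
    holding_mv: float = -63.0,
    probe_mv: float = 5.0,
    fs_hz: float = 10_000.0,
) -> ProtocolSpec:
    """5 mV probe step used to estimate Rm, Cm and Rs (100 ms baseline)."""
    return ProtocolSpec(
        kind="passive_probe",
        holding_mv=holding_mv,
        probe_mv=probe_mv,
        n_repeats=n_repeats,
        fs_hz=fs_hz,
        pre_s=0.1,
        step_dur_s=0.1,
        post_s=0.1,
    )


def step_protocol(
    fs_hz: float = 10_000.0,
    spermine: bool = False,
    drug_steady: bool = False,
) -> ProtocolSpec:
    """Seven 200 ms steps, -103 to +17 mV from -63 mV.

    With ``drug_steady=True`` the agonist conductance is held fully washed
    in, which is how the drug branch of an I-V family is acquired.
    """
    return ProtocolSpec(
        kind="step_iv",
        holding_mv=-63.0,
        step_voltages_mv=STEP_VOLTAGES_MV,
        fs_hz=fs_hz,
        spermine=spermine,
        drug_steady=drug_steady,
    )


def bath_protocol(
    drugs: tuple[DrugEvent, ...] | None = None,
    duration_s: float = 140.0,
    holding_mv: float = -63.0,
    fs_hz: float = 1_000.0,
    spermine: bool = False,
) -> ProtocolSpec:
    """Gap-free holding recording with slow bath drug application.

    Default schedule: 100 uM kainate from 20 s to 110 s.
    """
    if drugs is None:
        drugs = (DrugEvent("kainate", 100.0, 20.0, 110.0),)
    return ProtocolSpec(
        kind="agonist_bath",
        holding_mv=holding_mv,
        duration_s=duration_s,
        drugs=tuple(drugs),
        fs_hz=fs_hz,
        spermine=spermine,
    )


def rr_protocol(
    duration_s: float = 370.0,
    onset_s: float = 10.0,
    fs_hz: float = 5_000.0,
) -> ProtocolSpec:
    """Ruthenium Red EPSC recording at -83 mV (increased driving force)."""
    drugs = (DrugEvent("RR", 100.0, onset_s, duration_s),)
    return ProtocolSpec(
        kind="rr_epsc",
        holding_mv=-83.0,
        duration_s=duration_s,
        drugs=drugs,
        fs_hz=fs_hz,
    )


def minimal_stim_protocol(
    n_trials: int = 60,
    stim_time_s: float = 0.02,
    trial_dur_s: float = 0.1,
    fs_hz: float = 10_000.0,
) -> ProtocolSpec:
    """Minimal stimulation: 50-80 stimulus-locked trials at -63 mV."""
    return ProtocolSpec(
        kind="minimal_stim",
        holding_mv=-63.0,
        duration_s=trial_dur_s,
        stim_times_s=(stim_time_s,),
        n_trials=n_trials,
        fs_hz=fs_hz,
    )


def paired_pulse_protocol(
    n_trials: int = 10,
    first_stim_s: float = 0.02,
    trial_dur_s: float = 0.15,
    fs_hz: float = 10_000.0,
) -> ProtocolSpec:
    """Two strong pulses 25 ms apart, delivered ``n_trials`` times."""
    return ProtocolSpec(
        kind="paired_pulse",
        holding_mv=-63.0,
        duration_s=trial_dur_s,
        stim_times_s=(first_stim_s, first_stim_s + PAIRED_PULSE_INTERVAL_S),
        n_trials=n_trials,
        fs_hz=fs_hz,
    )
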