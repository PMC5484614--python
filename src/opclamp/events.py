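"""EPSC detection and synaptic measurements.

Detection follows threshold-search criteria for inward synaptic currents:
the gap-free trace is high-pass filtered at 2 Hz (zero-phase, 2nd order)
to remove baseline drift, the noise SD is estimated iteratively from
event-free stretches (detect, mask detections +/- 20 ms, re-estimate), the
amplitude threshold is 3x that SD, and candidate events must stay above
threshold for at least 1 ms with a rising phase faster than the decay
(operationalized as 20-80% rise time < decay time constant).  All
candidates are returned with accepted flags so rejections are auditable.

Frequency is summarized per minute of drug application; the comparison
window is minutes 3-6 after secretagogue onset, by which time the evoked
rate has reached its plateau.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .sweeps import SweepSet

__all__ = [
    "EventList",
    "detect_epscs",
    "frequency_timecourse",
    "unitary_epsc",
    "paired_pulse_ratio",
]

HIGHPASS_HZ = 2.0
THRESHOLD_SD = 3.0
MIN_DURATION_MS = 1.0
MASK_PAD_S = 0.02
MIN_TRACE_S = 10.0
SD_MAX_ITER = 10
NOISE_FLOOR_PA = 0.2  # threshold floor for (near-)noiseless traces
MERGE_GAP_MS = 1.0  # threshold crossings closer than this form one candidate
MEASURE_SMOOTH_MS = 0.5  # boxcar for peak/kinetics measurement (not detection)
BASELINE_MS = 10.0
DECAY_CAP_MS = 50.0


@dataclass
class EventList:
    """Detected (or ground-truth) synaptic events.

    ``table`` columns: onset_s, peak_time_s, amp_pa, duration_ms, rise_ms,
    decay_ms, accepted.  Times are strictly increasing.
    """

    table: pd.DataFrame
    noise_sd_pa: float = np.nan
    threshold_pa: float = np.nan
    meta: dict = field(default_factory=dict)

    @property
    def accepted(self) -> pd.DataFrame:
        return self.table.loc[self.table["accepted"].astype(bool)]

    @property
    def times(self) -> np.ndarray:
        return self.accepted["peak_time_s"].to_numpy()

    @property
    def amplitudes(self) -> np.ndarray:
        return self.accepted["amp_pa"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


def _filter_trace(x: np.ndarray, fs: float) -> np.ndarray:
    """Zero-phase 2nd-order 2 Hz high-pass (baseline-drift removal)."""
    sos_hp = signal.butter(2, HIGHPASS_HZ, "highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos_hp, x)


def _estimate_noise_sd(neg: np.ndarray, fs: float) -> float:
    """Iterative SD of event-free stretches: detect at 3 SD, mask, repeat.

    A small absolute floor keeps the threshold meaningful on noiseless
    synthetic traces, where the residual SD is filter ripple.
    """
    sd = max(1.4826 * float(np.median(np.abs(neg - np.median(neg)))), NOISE_FLOOR_PA)
    pad = int(MASK_PAD_S * fs)
    for _ in range(SD_MAX_ITER):
        above = neg > THRESHOLD_SD * sd
        mask = np.convolve(above.astype(float), np.ones(2 * pad + 1), "same") > 0
        clean = neg[~mask]
        if clean.size < 100:
            raise RuntimeError("noise SD estimation failed: no event-free segments")
        new_sd = max(float(np.std(clean)), NOISE_FLOOR_PA)
        if abs(new_sd - sd) / sd < 0.01:
            return new_sd
        sd = new_sd
    raise RuntimeError(f"noise SD estimation did not converge in {SD_MAX_ITER} iterations")


def detect_epscs(
    trace: SweepSet,
    threshold_sd: float = THRESHOLD_SD,
    min_duration_ms: float = MIN_DURATION_MS,
) -> EventList:
    """Detect inward synaptic events in a continuous recording.

    Requires a gap-free recording of at least 10 s at a constant holding
    potential.  Returns every candidate with its kinetics and an accepted
    flag (amplitude >= threshold, duration >= 1 ms above threshold, 20-80%
    rise faster than the decay time constant).
    """
    if trace.n_sweeps != 1:
        raise ValueError("detection expects one continuous (gap-free) sweep")
    if trace.duration < MIN_TRACE_S:
        raise ValueError(f"trace shorter than {MIN_TRACE_S:.0f} s")
    if np.ptp(trace.command[0]) != 0:
        raise ValueError("holding potential must be constant during detection")
    fs = trace.fs_hz
    y = _filter_trace(trace.data[0], fs)
    neg = -y  # inward events become positive excursions
    sd = _estimate_noise_sd(neg, fs)
    thr = threshold_sd * sd

    above = neg > thr
    idx = np.flatnonzero(above)
    if idx.size == 0:
        empty = pd.DataFrame(
            columns=["onset_s", "peak_time_s", "amp_pa", "duration_ms", "rise_ms", "decay_ms", "accepted"]
        )
        return EventList(empty, noise_sd_pa=sd, threshold_pa=thr)
    # crossings separated by less than a merge gap belong to one event
    # (broadband noise fragments a single suprathreshold excursion)
    gap = max(1, int(MERGE_GAP_MS * 1e-3 * fs))
    breaks = np.flatnonzero(np.diff(idx) > gap)
    region_starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    region_ends = np.concatenate((idx[breaks] + 1, [idx[-1] + 1]))

    n_base = int(BASELINE_MS * 1e-3 * fs)
    # Amplitudes and kinetics are measured on the raw trace against a local
    # pre-event baseline: the zero-phase high-pass used for detection puts
    # rate-dependent overshoots around events and would bias amplitudes.
    # A short median filter keeps single noisy samples from dominating the
    # peak and the 20-80% / 1/e crossings while leaving the peak intact.
    from scipy.ndimage import median_filter

    w = max(1, int(MEASURE_SMOOTH_MS * 1e-3 * fs)) | 1  # odd window
    ys = median_filter(trace.data[0], size=w, mode="nearest")
    rows = []
    for a, b in zip(region_starts, region_ends):
        dur_ms = (b - a) / fs * 1e3
        p = a + int(np.argmin(ys[a:b]))
        base = float(np.median(ys[max(0, a - n_base) : a])) if a > 0 else 0.0
        amp = base - float(ys[p])
        if amp <= 0:
            continue
        # 20-80% rise time: last crossings before the peak
        pre = base - ys[max(0, a - n_base) : p + 1]
        t20 = _last_below(pre, 0.2 * amp)
        t80 = _last_below(pre, 0.8 * amp)
        rise_ms = max((t80 - t20) / fs * 1e3, 1e3 / fs)
        # decay time constant: time from peak to 1/e of the amplitude
        cap = min(trace.n_samples, p + int(DECAY_CAP_MS * 1e-3 * fs))
        post = base - ys[p:cap]
        below = np.flatnonzero(post <= amp / np.e)
        decay_ms = (below[0] / fs * 1e3) if below.size else DECAY_CAP_MS
        accepted = (amp >= thr) and (dur_ms >= min_duration_ms) and (rise_ms < decay_ms)
        rows.append((a / fs, p / fs, amp, dur_ms, rise_ms, decay_ms, accepted))
    table = pd.DataFrame(
        rows,
        columns=["onset_s", "peak_time_s", "amp_pa", "duration_ms", "rise_ms", "decay_ms", "accepted"],
    )
    return EventList(table, noise_sd_pa=sd, threshold_pa=thr, meta=dict(trace.meta))


def _last_below(pre: np.ndarray, level: float) -> int:
    """Index (into ``pre``) of the last sample at/below ``level`` before its end."""
    below = np.flatnonzero(pre <= level)
    return int(below[-1]) if below.size else 0


def frequency_timecourse(
    events: EventList,
    drug_onset_s: float,
    recording_end_s: float,
    bin_s: float = 60.0,
    window_s: tuple[float, float] = (180.0, 360.0),
) -> tuple[pd.DataFrame, float]:
    """Per-minute event frequency and the minutes 3-6 window mean.

    ``window_s`` is relative to drug onset.  Raises if the window extends
    past the end of the recording.
    """
    if drug_onset_s + window_s[1] > recording_end_s + 1e-9:
        raise ValueError("analysis window extends past the end of the recording")
    t = events.times - drug_onset_s
    n_bins = int(np.floor((recording_end_s - drug_onset_s) / bin_s))
    counts, _ = np.histogram(t, bins=np.arange(0, (n_bins + 1) * bin_s, bin_s))
    per_minute = pd.DataFrame(
        {"minute": np.arange(n_bins), "freq_hz": counts / bin_s}
    )
    in_win = np.sum((t >= window_s[0]) & (t < window_s[1]))
    window_mean = float(in_win / (window_s[1] - window_s[0]))
    return per_minute, window_mean


def unitary_epsc(
    trials: SweepSet,
    response_window_s: float = 0.010,
) -> tuple[float, float]:
    """Unitary EPSC amplitude and success probability from minimal stimulation.

    Each stimulus-locked trial is classified success/failure by a 3x
    baseline-SD threshold crossing within ``response_window_s`` after the
    stimulus; the unitary amplitude is the mean peak of successes only.
    Returns ``(nan, 0.0)`` when no trial succeeds (undefined amplitude).
    """
    if not (50 <= trials.n_sweeps <= 80):
        warnings.warn(
            f"minimal stimulation protocol specifies 50-80 trials, got {trials.n_sweeps}",
            stacklevel=2,
        )
    stim = trials.meta.get("stim_times_s")
    if not stim:
        raise ValueError("stimulus time not marked in trials.meta['stim_times_s']")
    fs = trials.fs_hz
    i_stim = int(stim[0] * fs)
    i_end = i_stim + int(response_window_s * fs)
    base = trials.data[:, :i_stim]
    base_med = np.median(base, axis=1)
    base_sd = base.std(axis=1)
    seg = trials.data[:, i_stim:i_end]
    deficit = base_med[:, None] - seg  # inward positive
    peaks = deficit.max(axis=1)
    success = peaks > 3.0 * base_sd
    p = float(success.mean())
    if not success.any():
        return float("nan"), 0.0
    return float(peaks[success].mean()), p


def paired_pulse_ratio(sweeps: SweepSet, response_window_s: float = 0.020) -> float:
    """PPR = peak2 / peak1 from averaged paired-pulse sweeps.

    The decay of the first response is fitted with a single exponential
    from its peak to the second stimulus and subtracted (extrapolated)
    before measuring the second peak.  Requires two stimuli exactly 25 ms
    apart and at least one sweep (>= 10 repeats are averaged in practice).
    """
    stim = sweeps.meta.get("stim_times_s")
    if stim is None or len(stim) < 2:
        raise ValueError("need two marked stimulus times")
    s1, s2 = stim[0], stim[1]
    if abs((s2 - s1) - 0.025) > 1e-9:
        raise ValueError("paired-pulse interval must be exactly 25 ms")
    fs = sweeps.fs_hz
    y = sweeps.data.mean(axis=0)
    i1, i2 = int(s1 * fs), int(s2 * fs)
    base = float(np.median(y[max(0, i1 - int(0.01 * fs)) : i1]))
    d = base - y  # inward positive
    w = int(response_window_s * fs)
    p1_rel = int(np.argmax(d[i1 : i1 + w]))
    p1 = i1 + p1_rel
    peak1 = float(d[p1])
    if peak1 == 0:
        raise ValueError("first-pulse peak is zero; PPR undefined")
    # single-exponential fit of the decay between peak 1 and stimulus 2
    a = p1 + max(2, int(0.001 * fs))
    b = i2 - max(1, int(0.0005 * fs))
    extrap = np.zeros_like(d)
    if b - a > 4:
        seg = d[a:b]
        pos = seg > 0.02 * peak1
        if pos.sum() > 4:
            t = (np.arange(a, b)[pos] - p1) / fs
            coeffs = np.polyfit(t, np.log(seg[pos]), 1)
            if coeffs[0] < 0:
                amp0, tau = np.exp(coeffs[1]), -1.0 / coeffs[0]
                tt = (np.arange(i2, min(len(d), i2 + w)) - p1) / fs
                extrap[i2 : i2 + tt.size] = amp0 * np.exp(-tt / tau)
    d2 = d - extrap
    peak2 = float(np.max(d2[i2 : i2 + w]))
    return peak2 / peak1
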