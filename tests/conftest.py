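"""Shared fixtures: representative cells and reusable simulated recordings."""

from dataclasses import replace

import numpy as np
import pytest

from opclamp.synth import make_cell, probe_protocol, simulate_voltage_clamp


@pytest.fixture(scope="session")
def control_cell():
    cell, gt = make_cell("control", seed=42)
    return cell, gt


@pytest.fixture(scope="session")
def noiseless_passive_probe(control_cell):
    """Zero-noise probe recording of the passive (linear) version of a cell."""
    cell, gt = control_cell
    pcell = replace(cell.passive(), noise_sd_pa=0.0)
    sweeps = simulate_voltage_clamp(pcell, probe_protocol(n_repeats=2), seed=1)
    return sweeps, gt


def match_events(true_times: np.ndarray, detected_times: np.ndarray, tol_s: float = 0.005):
    """Greedy one-to-one matching of detected to ground-truth event times.

    Returns (n_matched, n_true, n_false_positive).
    """
    true_times = np.sort(np.asarray(true_times))
    det = np.sort(np.asarray(detected_times))
    used = np.zeros(det.size, dtype=bool)
    matched = 0
    j = 0
    for t in true_times:
        # advance to the window around t
        while j < det.size and det[j] < t - tol_s:
            j += 1
        k = j
        while k < det.size and det[k] <= t + tol_s:
            if not used[k]:
                used[k] = True
                matched += 1
                break
            k += 1
    return matched, true_times.size, int((~used).sum())
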