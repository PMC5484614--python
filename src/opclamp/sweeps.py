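"""Core container for episodic voltage-clamp data.

All currents are in pA, command voltages in mV, time in seconds unless a
name says otherwise.  A :class:`SweepSet` holds one protocol's worth of
sweeps for a single cell together with the per-cell metadata that the
analysis modules need (series resistance, capacitance, genotype label) and,
for synthetic data, the generator's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["SweepSet", "SimulationError"]


class SimulationError(RuntimeError):
    """Raised when the forward model produces a non-finite / runaway state."""


@dataclass
class SweepSet:
    """Multi-sweep current recording with its command-voltage protocol.

    Attributes
    ----------
    data :
        Recorded current, shape ``(n_sweeps, n_samples)``, pA.
    command :
        Command voltage, same shape as ``data``, mV.
    fs_hz :
        Sampling rate in Hz.
    meta :
        Per-cell metadata: ``holding_mv``, ``rs_mohm``, ``cm_pf``,
        ``genotype``, protocol ``kind``, drug schedule, stimulus times, ...
    ground_truth :
        Planted parameters for synthetic recordings (empty for real data).
    """

    data: np.ndarray
    command: np.ndarray
    fs_hz: float
    meta: dict[str, Any] = field(default_factory=dict)
    ground_truth: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        self.command = np.atleast_2d(np.asarray(self.command, dtype=float))
        if self.data.shape != self.command.shape:
            raise ValueError(
                f"data shape {self.data.shape} != command shape {self.command.shape}"
            )
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_sweeps(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def dt(self) -> float:
        """Sample interval in seconds."""
        return 1.0 / self.fs_hz

    @property
    def time(self) -> np.ndarray:
        """Time base in seconds, one entry per sample."""
        return np.arange(self.n_samples) / self.fs_hz

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs_hz
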