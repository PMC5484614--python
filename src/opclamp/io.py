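"""Serialization: HDF5 sweep sets, CSV tables with JSON parameter sidecars.

HDF5 layout for a sweep set::

    /data      (n_sweeps, n_samples) float64, pA
    /command   (n_sweeps, n_samples) float64, mV
    attrs: fs_hz
    /meta          JSON-encoded metadata (attrs['json'])
    /ground_truth  JSON-encoded ground truth (attrs['json'])

Ground truth round-trips unchanged (numpy arrays become lists and are
restored as arrays by the caller if needed; numeric values are preserved
exactly via JSON's float repr).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

import h5py
import numpy as np
import pandas as pd

from .sweeps import SweepSet

__all__ = [
    "write_sweepset_h5",
    "read_sweepset_h5",
    "write_table_csv",
    "read_table_csv",
]


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def _restore(obj: Any) -> Any:
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=obj.get("dtype", "float64"))
        return {k: _restore(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_restore(v) for v in obj]
    return obj


def write_sweepset_h5(path: str | Path, sweeps: SweepSet) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=sweeps.data)
        f.create_dataset("command", data=sweeps.command)
        f.attrs["fs_hz"] = sweeps.fs_hz
        f.create_group("meta").attrs["json"] = json.dumps(_jsonable(sweeps.meta))
        f.create_group("ground_truth").attrs["json"] = json.dumps(
            _jsonable(sweeps.ground_truth)
        )


def read_sweepset_h5(path: str | Path) -> SweepSet:
    with h5py.File(path, "r") as f:
        return SweepSet(
            data=f["data"][...],
            command=f["command"][...],
            fs_hz=float(f.attrs["fs_hz"]),
            meta=_restore(json.loads(f["meta"].attrs["json"])),
            ground_truth=_restore(json.loads(f["ground_truth"].attrs["json"])),
        )


def write_table_csv(
    path: str | Path,
    table: pd.DataFrame,
    params: dict[str, Any] | None = None,
) -> None:
    """Write a cohort table as CSV with a JSON sidecar of generator parameters.

    The sidecar lands next to the CSV as ``<name>.params.json`` and should
    always record the seed used.
    """
    path = Path(path)
    table.to_csv(path, index=False)
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".params.json")
        sidecar.write_text(json.dumps(_jsonable(params), indent=2))


def read_table_csv(path: str | Path) -> tuple[pd.DataFrame, dict[str, Any] | None]:
    path = Path(path)
    table = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".params.json")
    params = _restore(json.loads(sidecar.read_text())) if sidecar.exists() else None
    return table, params
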