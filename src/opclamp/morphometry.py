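"""Myelin morphometry: g-ratios, diameter distributions, figure densities
and 3D internode lengths.

Axon and fiber (outer myelin) circumferences are converted to diameters
assuming circular profiles (d = C / pi); the g-ratio is the axon diameter
over the fiber diameter, which equals the circumference ratio C_a / C_f
and is therefore unit-free.  Internode lengths are polyline arc lengths of
3D traces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FiberMetrics",
    "fiber_metrics",
    "myelin_figure_density",
    "density_ratio",
    "internode_length",
]

DIAMETER_BIN_UM = 0.1


@dataclass
class FiberMetrics:
    table: pd.DataFrame  # valid rows with d_axon_um, d_fiber_um, g
    rejected: pd.DataFrame  # rows violating 0 < C_a < C_f, with reasons
    diameter_hist: pd.DataFrame  # per-group binned axon-diameter frequencies


def fiber_metrics(records: pd.DataFrame, bin_um: float = DIAMETER_BIN_UM) -> FiberMetrics:
    """Per-fiber diameters and g-ratios from circumference pairs.

    ``records`` needs columns ``c_axon_um`` and ``c_fiber_um`` (grouping
    columns such as ``genotype``/``animal_id`` are carried through).  Rows
    with C_a >= C_f or non-positive circumferences are rejected row-wise
    and reported, not silently dropped.  Fibers with g above 0.98 are kept
    but flagged (``near_unity_g``) as boundary cases.
    """
    df = records.copy()
    bad_pos = ~((df["c_axon_um"] > 0) & (df["c_fiber_um"] > 0))
    bad_order = df["c_axon_um"] >= df["c_fiber_um"]
    bad = bad_pos | bad_order
    rejected = df[bad].copy()
    rejected["reason"] = np.where(
        bad_pos[bad], "non-positive circumference", "C_axon >= C_fiber"
    )
    ok = df[~bad].copy()
    ok["d_axon_um"] = ok["c_axon_um"] / np.pi
    ok["d_fiber_um"] = ok["c_fiber_um"] / np.pi
    ok["g"] = ok["c_axon_um"] / ok["c_fiber_um"]
    ok["near_unity_g"] = ok["g"] > 0.98

    group_col = "genotype" if "genotype" in ok.columns else None
    if len(ok):
        edges = np.arange(0.0, ok["d_axon_um"].max() + 2 * bin_um, bin_um)
        if group_col:
            hists = []
            for g, sub in ok.groupby(group_col):
                counts, _ = np.histogram(sub["d_axon_um"], bins=edges)
                hists.append(
                    pd.DataFrame(
                        {group_col: g, "bin_left_um": edges[:-1], "count": counts}
                    )
                )
            hist = pd.concat(hists, ignore_index=True)
        else:
            counts, _ = np.histogram(ok["d_axon_um"], bins=edges)
            hist = pd.DataFrame({"bin_left_um": edges[:-1], "count": counts})
    else:
        hist = pd.DataFrame(columns=["bin_left_um", "count"])
    return FiberMetrics(table=ok, rejected=rejected, diameter_hist=hist)


def myelin_figure_density(count: int, area_um2: float) -> float:
    """Myelin figures per unit area (figures / um^2)."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return count / area_um2


def density_ratio(
    counts: pd.DataFrame,
    mutant: str,
    control: str = "control",
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Mutant/control mean figure-density ratio with a bootstrap CI.

    ``counts`` has per-animal rows (genotype, count, area_um2); the CI
    resamples animals within each genotype.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dens = counts.assign(density=counts["count"] / counts["area_um2"])
    d_m = dens.loc[dens["genotype"] == mutant, "density"].to_numpy()
    d_c = dens.loc[dens["genotype"] == control, "density"].to_numpy()
    if d_m.size == 0 or d_c.size == 0:
        raise ValueError("both genotypes must be present")
    ratio = d_m.mean() / d_c.mean()
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = (
            rng.choice(d_m, d_m.size).mean() / rng.choice(d_c, d_c.size).mean()
        )
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return float(ratio), (float(lo), float(hi))


def internode_length(points_um: np.ndarray) -> float:
    """Arc length (um) of a 3D internode polyline: sum of segment lengths."""
    pts = np.asarray(points_um, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("internode trace needs >= 2 points of (x, y, z)")
    seg = np.diff(pts, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    if np.any(lengths == 0):
        raise ValueError("consecutive trace points must be distinct")
    return float(lengths.sum())
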