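"""Synthetic histology and morphometry cohorts with planted genotype effects.

Count tables emulate per-field marker counts in confocal images of corpus
callosum (3-4 fields per animal), with litter and animal random effects on
true density and Poisson sampling of counts.  Mutant densities are scaled
by the preset's planted effect; OP density and proliferation indices are
planted nulls.  The caspase cohort plants a fold-change of the apoptotic
fraction on top of a litter random effect, which the litter-normalization
procedure is designed to remove.  Fiber tables plant diameter and g-ratio
distributions (genotype affects only the number of myelin figures per
area, never g or internode length).
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd

from .presets import (
    CONTROL_CASPASE_FRACTION,
    GenotypePreset,
    OL_DENSITY_PER_MM2,
    OP_DENSITY_PER_MM2,
    get_preset,
)

__all__ = [
    "simulate_histology_counts",
    "simulate_caspase_cohort",
    "simulate_fiber_geometry",
    "random_walk_internode",
]


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None) -> np.ndarray | float:
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv**2))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_histology_counts(
    preset: str | GenotypePreset,
    age: str = "P14",
    n_litters: int = 7,
    controls_per_litter: int = 2,
    mutants_per_litter: int = 2,
    fields_per_animal: tuple[int, int] = (3, 4),
    field_area_mm2: float = 0.30,
    litter_cv: float = 0.06,
    animal_cv: float = 0.06,
    edu_index: float = 0.25,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Generate a per-field count table for a mutant-vs-control cohort.

    Each litter contains both control and mutant animals (litter
    normalization downstream requires within-litter controls).  Markers:
    ``CC1`` (oligodendrocytes; mutant density scaled by the preset's
    ``ol_density_effect[age]``), ``Pdgfra`` (OPs; planted null) and
    ``EdU+Pdgfra`` (double-positive subset, binomial at a genotype-invariant
    labelling index).

    Returns the tidy table (litter_id, animal_id, genotype, age, field_id,
    area_mm2, marker, count) and the ground-truth dict.
    """
    preset = get_preset(preset)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if n_litters < 2:
        raise ValueError("need >= 2 litters, each with control and mutant animals")
    ol_ctrl = OL_DENSITY_PER_MM2[age]
    effect = preset.ol_density_effect.get(age, 0.0)
    rows = []
    for lit in range(n_litters):
        lf = _lognormal_factor(rng, litter_cv)
        for geno, n_animals in (("control", controls_per_litter), (preset.name, mutants_per_litter)):
            scale = 1.0 if geno == "control" else 1.0 - effect
            for a in range(n_animals):
                af = _lognormal_factor(rng, animal_cv)
                d_ol = ol_ctrl * lf * af * scale
                d_op = OP_DENSITY_PER_MM2 * lf * _lognormal_factor(rng, animal_cv)
                animal_id = f"L{lit}_{geno}_{a}"
                n_fields = rng.integers(fields_per_animal[0], fields_per_animal[1] + 1)
                for f in range(n_fields):
                    area = field_area_mm2 * rng.uniform(0.9, 1.1)
                    if area <= 0:
                        raise ValueError("field area must be positive")
                    n_op = rng.poisson(d_op * area)
                    n_edu = rng.binomial(n_op, edu_index) if n_op > 0 else 0
                    for marker, count in (
                        ("CC1", rng.poisson(d_ol * area)),
                        ("Pdgfra", n_op),
                        ("EdU+Pdgfra", n_edu),
                    ):
                        rows.append(
                            (lit, animal_id, geno, age, f, area, marker, int(count))
                        )
    table = pd.DataFrame(
        rows,
        columns=[
            "litter_id",
            "animal_id",
            "genotype",
            "age",
            "field_id",
            "area_mm2",
            "marker",
            "count",
        ],
    )
    gt = {
        "preset": preset.name,
        "age": age,
        "ol_density_control": ol_ctrl,
        "ol_effect": effect,
        "planted_ol_ratio": 1.0 - effect,
        "op_density": OP_DENSITY_PER_MM2,
        "edu_index": edu_index,
    }
    return table, gt


def simulate_caspase_cohort(
    preset: str | GenotypePreset,
    n_litters: int = 6,
    controls_per_litter: int = 3,
    mutants_per_litter: int = 3,
    control_fraction: float | None = None,
    litter_cv: float = 0.12,
    animal_cv: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, dict[str, Any]]:
    """Per-animal fractions of Olig2+ cells positive for cleaved Caspase-3.

    The control fraction defaults to the experiment-specific control mean
    for the preset (22.7% for the double-knockout series, 24.8% for the
    triple).  Mutant animals get the litter's base fraction times the
    preset's ``caspase_factor``.  The litter random effect (CV
    ``litter_cv``) is common to all animals of a litter, so within-litter
    normalization removes it; the within-litter animal CV is what limits
    recovery of the planted fold-change.
    """
    preset = get_preset(preset)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if control_fraction is None:
        control_fraction = CONTROL_CASPASE_FRACTION.get(preset.name, 0.227)
    rows = []
    for lit in range(n_litters):
        base = control_fraction * _lognormal_factor(rng, litter_cv)
        for geno, n_animals, factor in (
            ("control", controls_per_litter, 1.0),
            (preset.name, mutants_per_litter, preset.caspase_factor),
        ):
            for a in range(n_animals):
                frac = base * factor * _lognormal_factor(rng, animal_cv)
                rows.append((lit, f"L{lit}_{geno}_{a}", geno, float(np.clip(frac, 0.0, 1.0))))
    table = pd.DataFrame(rows, columns=["litter_id", "animal_id", "genotype", "fraction"])
    gt = {
        "preset": preset.name,
        "control_fraction": control_fraction,
        "caspase_factor": preset.caspase_factor,
    }
    return table, gt


def random_walk_internode(
    rng: np.random.Generator,
    arc_length_um: float,
    step_um: float = 1.0,
    wobble: float = 0.15,
) -> np.ndarray:
    """3D polyline with exactly the requested arc length.

    A forward-biased random walk: each segment has length ``step_um`` (the
    last one shorter to land exactly on ``arc_length_um``) with small
    angular wobble, emulating a traced internode in a confocal stack.
    """
    n_full, rem = divmod(arc_length_um, step_um)
    lengths = [step_um] * int(n_full) + ([rem] if rem > 1e-12 else [])
    direction = np.array([1.0, 0.0, 0.0])
    pts = [np.zeros(3)]
    for ln in lengths:
        direction = direction + wobble * rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        pts.append(pts[-1] + ln * direction)
    return np.asarray(pts)


def simulate_fiber_geometry(
    preset: str | GenotypePreset,
    n_animals: int = 5,
    fibers_per_animal: int = 80,
    internodes_per_animal: int = 10,
    axon_diameter_um: tuple[float, float] = (0.8, 0.25),  # lognormal mean, CV
    g_ratio: tuple[float, float] = (0.78, 0.03),  # truncated normal on (0, 1)
    figure_density_per_um2: float = 0.06,
    field_area_um2: float = 210.0 * 160.0,
    internode_length_um: tuple[float, float] = (50.0, 10.0),
    measurement_noise_cv: float = 0.0,
    animal_cv: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, list[dict[str, Any]], dict[str, Any]]:
    """Generate circumference pairs, myelin-figure counts and internodes.

    Genotype scales only the myelin-figure count per area (by
    ``1 - myelin_density_effect``); the g-ratio and internode-length
    distributions are planted nulls.  Circumferences are C = pi * d with
    optional multiplicative measurement noise.

    Returns ``(fibers, figure_counts, internodes, ground_truth)`` where
    ``fibers`` has columns (animal_id, genotype, c_axon_um, c_fiber_um),
    ``figure_counts`` has per-animal (animal_id, genotype, count,
    area_um2) and ``internodes`` is a list of dicts with a ``points_um``
    polyline, its planted ``arc_length_um`` and labels.
    """
    preset = get_preset(preset)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    g_mu, g_sd = g_ratio
    if not (0.0 < g_mu < 1.0):
        raise ValueError("g-ratio distribution must be supported in (0, 1)")
    density = figure_density_per_um2 * (1.0 - preset.myelin_density_effect)
    fiber_rows = []
    count_rows = []
    internodes: list[dict[str, Any]] = []
    for a in range(n_animals):
        animal = f"{preset.name}_{a}"
        d_axon = axon_diameter_um[0] * _lognormal_factor(
            rng, axon_diameter_um[1], fibers_per_animal
        )
        g = rng.normal(g_mu, g_sd, fibers_per_animal)
        g = np.clip(g, 1e-3, 1.0 - 1e-3)
        c_axon = np.pi * d_axon
        c_fiber = c_axon / g
        if measurement_noise_cv > 0:
            c_axon = c_axon * _lognormal_factor(rng, measurement_noise_cv, fibers_per_animal)
            c_fiber = c_fiber * _lognormal_factor(rng, measurement_noise_cv, fibers_per_animal)
        for ca, cf in zip(c_axon, c_fiber):
            fiber_rows.append((animal, preset.name, float(ca), float(cf)))
        count = rng.poisson(density * _lognormal_factor(rng, animal_cv) * field_area_um2)
        count_rows.append((animal, preset.name, int(count), field_area_um2))
        for i in range(internodes_per_animal):
            arc = max(rng.normal(*internode_length_um), 5.0)
            internodes.append(
                {
                    "animal_id": animal,
                    "genotype": preset.name,
                    "cell_id": f"{animal}_ol{i}",
                    "arc_length_um": float(arc),
                    "points_um": random_walk_internode(rng, arc),
                }
            )
    fibers = pd.DataFrame(
        fiber_rows, columns=["animal_id", "genotype", "c_axon_um", "c_fiber_um"]
    )
    counts = pd.DataFrame(count_rows, columns=["animal_id", "genotype", "count", "area_um2"])
    gt = {
        "preset": preset.name,
        "g_ratio_mean": g_mu,
        "g_ratio_sd": g_sd,
        "figure_density_per_um2": density,
        "planted_density_ratio": 1.0 - preset.myelin_density_effect,
        "axon_diameter_um": axon_diameter_um,
    }
    return fibers, counts, internodes, gt
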