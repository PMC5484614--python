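"""Single-compartment OP model parameters and the cell factory.

OPs in developing white matter are small and electrotonically compact
(Rm >= 1 GOhm, Cm <= 35 pF), so a single compartment clamped through an
access resistance is an adequate forward model.  A cell carries a leak
conductance, Hodgkin-Huxley style m^3 h sodium channels (OPs are defined
in part by the presence of a transient inward Na+ current), and two
agonist-gated conductances with a 0 mV reversal potential: an AMPAR
component (``ga_max_ns``, GYKI-sensitive, optionally rectifying via a
polyamine-block Boltzmann) and a kainate-receptor component
(``gk_max_ns``, GYKI-resistant).

The absolute conductance scale is set so that a control cell's total
kainate-evoked current density at -63 mV is ``KAINATE_DENSITY_PA_PER_PF``;
genotype presets scale the total by ``kainate_density_rel`` and split it
by ``ampar_fraction``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .presets import GenotypePreset, get_preset

__all__ = ["CellModelParams", "make_cell", "KAINATE_DENSITY_PA_PER_PF"]

#: Control total kainate-evoked current density at -63 mV (pA/pF).  The
#: absolute scale is a free generator parameter (only relative effects are
#: constrained); 10 pA/pF gives a few hundred pA in a typical OP.
KAINATE_DENSITY_PA_PER_PF = 10.0

E_GLU_MV = 0.0
E_NA_MV = 60.0
JUNCTION_POTENTIAL_MV = -3.0


@dataclass(frozen=True)
class CellModelParams:
    """Parameters of one simulated OP (units in field names)."""

    rm_gohm: float
    cm_pf: float
    rs_mohm: float
    e_leak_mv: float = -63.0
    # voltage-gated Na+ channel, m^3 h kinetics
    gna_max_ns: float = 10.0
    na_m_half_mv: float = -30.0
    na_m_slope_mv: float = 7.0
    na_tau_m_ms: float = 0.3
    na_h_half_mv: float = -55.0
    na_h_slope_mv: float = 7.0
    na_tau_h_ms: float = 2.0
    e_na_mv: float = E_NA_MV
    # agonist-gated conductances (reversal 0 mV)
    ga_max_ns: float = 0.0  # AMPAR component (GYKI-sensitive)
    gk_max_ns: float = 0.0  # kainate-receptor component (GYKI-resistant)
    # polyamine block of GluA2-lacking AMPARs: open fraction
    # f(V) = 1 / (1 + exp((V - vh) / k)); only active with intracellular
    # spermine in a rectifying genotype.
    rectifying: bool = False
    rect_vh_mv: float = -20.0
    rect_k_mv: float = 15.0
    e_glu_mv: float = E_GLU_MV
    # recording model
    noise_sd_pa: float = 2.0
    junction_potential_mv: float = JUNCTION_POTENTIAL_MV
    # drug wash kinetics (bath application)
    tau_wash_on_s: float = 20.0
    tau_wash_off_s: float = 60.0
    meta: dict[str, Any] = field(default_factory=dict)

    @property
    def g_leak_ns(self) -> float:
        return 1.0 / self.rm_gohm

    def passive(self) -> "CellModelParams":
        """Copy with all active conductances removed (linear cell)."""
        return replace(self, gna_max_ns=0.0, ga_max_ns=0.0, gk_max_ns=0.0)


def make_cell(
    preset: str | GenotypePreset,
    seed: int | np.random.Generator,
    density_cv: float = 0.15,
    ampar_fraction_sd: float = 0.03,
) -> tuple[CellModelParams, dict[str, Any]]:
    """Draw one OP from a genotype preset.

    Passive properties are drawn from distributions that satisfy the OP
    inclusion criteria (Rm >= 1 GOhm, Cm <= 35 pF): Rm lognormal around
    1.8 GOhm truncated at 1 GOhm, Cm uniform within 12-34 pF, Rs uniform
    10-20 MOhm (the typical monitored range).  Agonist conductances are the
    control density scaled by the preset's ``kainate_density_rel`` times a
    per-cell lognormal factor with coefficient of variation ``density_cv``;
    the AMPAR/KAR split jitters around ``ampar_fraction`` with SD
    ``ampar_fraction_sd``.

    With the same ``seed``, different presets reuse identical base draws,
    so preset-to-preset conductance ratios are exact in expectation and per
    matched cell pairs.

    Returns the cell and a ground-truth dict of every planted value.
    """
    preset = get_preset(preset)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    rm = 0.0
    while rm < 1.0:
        rm = rng.lognormal(mean=np.log(1.8), sigma=0.25)
    cm = rng.uniform(12.0, 34.0)
    rs = rng.uniform(10.0, 20.0)
    gna = rng.lognormal(mean=np.log(10.0), sigma=0.2)

    sigma = np.sqrt(np.log(1.0 + density_cv**2))
    density_jitter = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma)
    g_total = (
        KAINATE_DENSITY_PA_PER_PF
        / 63.0  # nS/pF at a 63 mV driving force
        * cm
        * preset.kainate_density_rel
        * density_jitter
    )
    frac = float(np.clip(rng.normal(preset.ampar_fraction, ampar_fraction_sd), 0.0, 1.0))

    cell = CellModelParams(
        rm_gohm=rm,
        cm_pf=cm,
        rs_mohm=rs,
        gna_max_ns=gna,
        ga_max_ns=g_total * frac,
        gk_max_ns=g_total * (1.0 - frac),
        rectifying=preset.ampar_rectifying,
        meta={"genotype": preset.name},
    )
    ground_truth = {
        "genotype": preset.name,
        "rm_gohm": rm,
        "cm_pf": cm,
        "rs_mohm": rs,
        "gna_max_ns": gna,
        "g_total_ns": g_total,
        "ga_max_ns": cell.ga_max_ns,
        "gk_max_ns": cell.gk_max_ns,
        "ampar_fraction": frac,
        "density_jitter": density_jitter,
        "kainate_density_pa_per_pf": KAINATE_DENSITY_PA_PER_PF
        * preset.kainate_density_rel
        * density_jitter,
    }
    return cell, ground_truth
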