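"""Genotype presets for the synthetic-data generator.

Each preset bundles the relative functional effects of deleting AMPAR
subunits from the oligodendrocyte lineage, expressed against the
``control`` genotype (a *Gria3*-null background with intact GluA2/GluA4,
which is the comparison group throughout):

* ``control`` — full AMPAR complement (GluA2/3/4 background control).
* ``dko``     — GluA2/GluA3 double knockout: roughly half the
  kainate-evoked current density, inwardly rectifying AMPARs (GluA2 absent,
  spermine block at positive potentials), ~70% fewer secretagogue-evoked
  EPSCs, ~27% fewer oligodendrocytes at P14, apoptotic fraction up ~1.19x,
  ~20% fewer myelin figures.
* ``tko``     — GluA2/3/4 triple knockout: residual (mostly
  kainate-receptor) current ~23% of the dko level, GYKI-sensitive fraction
  down to ~0.39, essentially no EPSCs, ~22% fewer oligodendrocytes at P14,
  apoptotic fraction up ~1.24x.

EPSC amplitude parameters are deliberately identical across presets: the
knockouts change how many functional synapses there are, not the quantal
amplitude at the synapses that remain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenotypePreset",
    "PRESETS",
    "get_preset",
    "CONTROL_CASPASE_FRACTION",
    "OL_DENSITY_PER_MM2",
    "OP_DENSITY_PER_MM2",
]

#: Control fraction of Olig2+ cells positive for cleaved Caspase-3, by
#: experiment series (double- and triple-knockout cohorts were scored
#: against different control litters).
CONTROL_CASPASE_FRACTION = {"dko": 0.227, "tko": 0.248}

#: Control CC1+ oligodendrocyte density (cells/mm^2) by age, a realistic
#: scale for developing corpus callosum.  The generator only needs a scale;
#: effects are always expressed as fractions of control.
OL_DENSITY_PER_MM2 = {"P7": 600.0, "P14": 1000.0, "P21": 1300.0, "P70": 1500.0}

#: Control Pdgfra+ OP density (cells/mm^2), unaffected by genotype.
OP_DENSITY_PER_MM2 = 450.0


@dataclass(frozen=True)
class GenotypePreset:
    """Relative genotype effects planted by the generator.

    ``kainate_density_rel`` scales the total kainate-evoked current density
    at -63 mV; ``ampar_fraction`` is the fraction of that current carried by
    AMPARs (i.e. blocked by GYKI); ``synapse_rate_rel`` scales the
    secretagogue-evoked EPSC rate.  Cohort effects: ``ol_density_effect``
    is the fractional reduction of CC1+ density by age, ``caspase_factor``
    the fold-change of the apoptotic fraction, ``myelin_density_effect``
    the fractional reduction of myelin figures per area.
    """

    name: str
    kainate_density_rel: float = 1.0
    ampar_fraction: float = 0.80
    ampar_rectifying: bool = False
    synapse_rate_rel: float = 1.0
    epsc_amplitude_mean_pa: float = 20.0
    epsc_amplitude_sd_pa: float = 5.0
    ol_density_effect: dict[str, float] = field(default_factory=dict)
    caspase_factor: float = 1.0
    myelin_density_effect: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 < self.kainate_density_rel <= 1.0):
            raise ValueError("kainate_density_rel must be in (0, 1]")
        if not (0.0 <= self.ampar_fraction <= 1.0):
            raise ValueError("ampar_fraction must be in [0, 1]")
        if not (0.0 < self.synapse_rate_rel <= 1.0):
            raise ValueError("synapse_rate_rel must be in (0, 1]")


PRESETS: dict[str, GenotypePreset] = {
    "control": GenotypePreset(
        name="control",
        kainate_density_rel=1.0,
        ampar_fraction=0.80,
        ampar_rectifying=False,
        synapse_rate_rel=1.0,
        ol_density_effect={"P7": 0.0, "P14": 0.0, "P21": 0.0, "P70": 0.0},
        caspase_factor=1.0,
        myelin_density_effect=0.0,
    ),
    # GluA2/3 double knockout: ~47% less kainate-evoked current density,
    # rectifying (GluA2-lacking) AMPARs, EPSC frequency ~30% of control.
    "dko": GenotypePreset(
        name="dko",
        kainate_density_rel=0.53,
        ampar_fraction=0.80,
        ampar_rectifying=True,
        synapse_rate_rel=0.30,
        ol_density_effect={"P7": 0.22, "P14": 0.27, "P21": 0.0, "P70": 0.0},
        caspase_factor=1.194,
        myelin_density_effect=0.20,
    ),
    # GluA2/3/4 triple knockout: residual current 23% of the dko level
    # (0.23 * 0.53 of control), mostly kainate-receptor mediated (GYKI
    # blocks only ~39%), near-linear I-V, almost no EPSCs.
    "tko": GenotypePreset(
        name="tko",
        kainate_density_rel=0.23 * 0.53,
        ampar_fraction=0.39,
        ampar_rectifying=False,
        synapse_rate_rel=0.01,
        ol_density_effect={"P7": 0.22, "P14": 0.22, "P21": 0.22, "P70": 0.26},
        caspase_factor=1.242,
        myelin_density_effect=0.22,
    ),
}


def get_preset(name: str | GenotypePreset) -> GenotypePreset:
    """Look up a named preset, passing through user-supplied overrides."""
    if isinstance(name, GenotypePreset):
        return name
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown genotype preset {name!r}; expected one of {sorted(PRESETS)}"
        ) from None
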