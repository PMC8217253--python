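"""Neutron scattering length densities of solvents, films and surfactants.

The contrast-variation scheme of a solid–liquid reflectometry experiment rests
on simple SLD arithmetic: the coherent scattering length density of a material
follows from its chemical formula and mass density, and solvent contrasts are
volume-fraction mixtures of the H2O- and D2O-based buffer endpoints.  This
module provides that arithmetic, a small bundled table of bound coherent
scattering lengths, and the standard contrast series (hPBS, silicon-matched
water, dPBS) used for pellicle experiments.

Units: scattering length densities are expressed throughout in 1e-6 Å^-2;
densities in g/cm^3.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

__all__ = [
    "ScatteringMaterial",
    "ContrastDefinition",
    "scattering_length_table",
    "sld_from_formula",
    "mix_sld",
    "contrast_series",
    "HPBS_SLD",
    "DPBS_SLD",
    "SMW_PBS_SLD",
    "WATER_DENSITY",
    "HEAVY_WATER_DENSITY",
    "SILICA_DENSITY",
]

_AVOGADRO = 6.02214076e23

# Default mass densities (g/cm^3) at room temperature.
WATER_DENSITY = 0.997
HEAVY_WATER_DENSITY = 1.105
SILICA_DENSITY = 2.2


def scattering_length_table() -> dict[str, dict[str, float]]:
    """Bound coherent scattering lengths (fm) and atomic masses (g/mol).

    Loaded from the bundled JSON table; H and D are distinct entries.
    """
    text = resources.files("pellifilm.data").joinpath("scattering_lengths.json").read_text()
    return json.loads(text)["elements"]


def sld_from_formula(formula: Mapping[str, float], mass_density: float) -> float:
    """Coherent SLD (1e-6 Å^-2) of a material from formula and mass density.

    SLD = sum(count_i * b_i) / V_molecule with the molecular volume taken from
    the molar mass and the bulk mass density.

    Parameters
    ----------
    formula
        Element -> count map, e.g. ``{"H": 2, "O": 1}``.  Isotopes H and D are
        distinct symbols.  Counts must be positive.
    mass_density
        Bulk mass density in g/cm^3; must be positive.
    """
    if not formula:
        raise ValueError("formula is empty; cannot derive an SLD")
    if mass_density <= 0:
        raise ValueError(f"mass_density must be positive, got {mass_density}")
    table = scattering_length_table()
    b_sum_fm = 0.0
    molar_mass = 0.0
    for element, count in formula.items():
        if element not in table:
            raise KeyError(
                f"element {element!r} is not in the bundled scattering-length table"
            )
        if count <= 0:
            raise ValueError(f"formula count for {element!r} must be positive, got {count}")
        b_sum_fm += count * table[element]["b_coh_fm"]
        molar_mass += count * table[element]["mass"]
    # b in cm: 1 fm = 1e-13 cm; molecular volume in cm^3 = M / (rho * N_A).
    # SLD in cm^-2 = rho * N_A * b_sum / M; 1e10 cm^-2 == 1e-6 Å^-2.
    sld_cm2 = mass_density * _AVOGADRO * b_sum_fm * 1e-13 / molar_mass
    return sld_cm2 / 1e10


def mix_sld(components: Sequence[tuple[float, float]]) -> float:
    """Volume-fraction weighted mean SLD of a mixture.

    ``components`` is a sequence of ``(sld, volume_fraction)`` pairs; the
    fractions must be non-negative and sum to 1 within 1e-6.
    """
    if not components:
        raise ValueError("no components given")
    fractions = [f for _, f in components]
    if any(f < 0 for f in fractions):
        raise ValueError(f"volume fractions must be non-negative, got {fractions}")
    total = sum(fractions)
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"volume fractions must sum to 1, got sum {total}")
    return sum(sld * f for sld, f in components)


@dataclass(frozen=True)
class ScatteringMaterial:
    """A chemical species with a coherent neutron scattering length density.

    The SLD may be supplied explicitly (e.g. for a surfactant whose value is
    known from the literature) or derived from ``formula`` and
    ``mass_density``.
    """

    name: str
    formula: Mapping[str, float] | None = None
    mass_density: float | None = None
    sld: float | None = None

    def __post_init__(self) -> None:
        if self.sld is None:
            if self.formula is None or self.mass_density is None:
                raise ValueError(
                    f"material {self.name!r}: give either an explicit sld or "
                    "both formula and mass_density"
                )
            object.__setattr__(
                self, "sld", sld_from_formula(self.formula, self.mass_density)
            )


@dataclass(frozen=True)
class ContrastDefinition:
    """One solvent contrast: a D2O/H2O buffer mixture and its SLD."""

    name: str
    solvent_sld: float
    d2o_volume_fraction: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.d2o_volume_fraction <= 1.0:
            raise ValueError(
                f"d2o_volume_fraction must lie in [0, 1], got {self.d2o_volume_fraction}"
            )
        expected = mix_sld(
            [(DPBS_SLD, self.d2o_volume_fraction), (HPBS_SLD, 1.0 - self.d2o_volume_fraction)]
        )
        if abs(self.solvent_sld - expected) > 0.01:
            raise ValueError(
                f"contrast {self.name!r}: solvent_sld {self.solvent_sld} is not the "
                f"{self.d2o_volume_fraction:.2f} D2O mix of the buffer endpoints "
                f"(expected {expected:.3f})"
            )


# Buffer endpoint SLDs.  PBS salts are dilute (~150 mM) and are neglected: the
# buffers carry the SLD of the water they are prepared with.
HPBS_SLD = sld_from_formula({"H": 2, "O": 1}, WATER_DENSITY)
DPBS_SLD = sld_from_formula({"D": 2, "O": 1}, HEAVY_WATER_DENSITY)
SMW_PBS_SLD = mix_sld([(DPBS_SLD, 0.38), (HPBS_SLD, 0.62)])

# Surfactant SLDs (1e-6 Å^-2): amphoteric cocamidopropyl betaine, chain
# deuterated and fully hydrogenated pentaethylene glycol monododecyl ether.
CAPB = ScatteringMaterial("CAPB", sld=0.36)
D_C12E5 = ScatteringMaterial("dC12E5", sld=3.76)
H_C12E5 = ScatteringMaterial("hC12E5", sld=0.129)


def contrast_series(
    d2o_fractions: Sequence[float], names: Sequence[str] | None = None
) -> list[ContrastDefinition]:
    """Build the solvent contrast series for a set of D2O volume fractions.

    Each contrast's SLD is the linear mix of the hPBS/dPBS endpoints.  The
    conventional three-contrast series is ``[0.0, 0.38, 1.0]`` (hPBS,
    silicon-matched water, dPBS).
    """
    contrasts = []
    for i, frac in enumerate(d2o_fractions):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"D2O volume fraction must lie in [0, 1], got {frac}")
        sld = mix_sld([(DPBS_SLD, frac), (HPBS_SLD, 1.0 - frac)])
        name = names[i] if names is not None else f"d2o_{frac:.2f}"
        contrasts.append(ContrastDefinition(name, sld, frac))
    return contrasts


def standard_contrasts() -> list[ContrastDefinition]:
    """hPBS, silicon-matched-water PBS and dPBS, in that order."""
    return contrast_series([0.0, 0.38, 1.0], names=["hPBS", "smwPBS", "dPBS"])
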