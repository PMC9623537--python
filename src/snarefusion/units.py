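"""Physical constants, the aqueous medium, and vesicle geometry.

Everything downstream of this module is denominated in thermal energy
(kBT), so the conversions collected here are the single bridge between
SI joules, kBT and the pN·nm scale natural to single-molecule mechanics.
All internal arithmetic is SI; interfaces accept and emit nm, kBT, pN
and seconds where those are the conventional units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "BOLTZMANN_J_PER_K",
    "AVOGADRO_PER_MOL",
    "PA_PER_ATM",
    "Medium",
    "VesicleGeometry",
    "thermal_energy",
    "joules_to_kbt",
    "kbt_to_joules",
    "kbt_to_pn_nm",
    "pn_nm_to_kbt",
    "lipids_per_vesicle",
    "vesicle_number_density",
]

BOLTZMANN_J_PER_K = 1.380649e-23
AVOGADRO_PER_MOL = 6.02214076e23
PA_PER_ATM = 101325.0


class InvalidParameterError(ValueError):
    """A physical parameter is outside its admissible domain."""


@dataclass(frozen=True)
class Medium:
    """Aqueous phase: temperature in kelvin, dynamic viscosity in Pa·s.

    Defaults are water at laboratory temperature (298.15 K, 1 mPa·s),
    the conditions of the standard bulk lipid-mixing assay.
    """

    temperature: float = 298.15
    viscosity: float = 1.0e-3

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise InvalidParameterError(
                f"temperature must be > 0 K, got {self.temperature}"
            )
        if not self.viscosity > 0:
            raise InvalidParameterError(
                f"viscosity must be > 0 Pa·s, got {self.viscosity}"
            )

    @property
    def thermal_energy_j(self) -> float:
        """kB·T in joules."""
        return BOLTZMANN_J_PER_K * self.temperature


@dataclass(frozen=True)
class VesicleGeometry:
    """Spherical-shell vesicle: outer radius, bilayer thickness, area per lipid.

    All lengths in nm, area in nm². The defaults describe the 50-nm-diameter
    monodisperse SUVs of the reconstitution assays: 25 nm outer radius,
    5 nm bilayer, 0.65 nm² per lipid head group.
    """

    outer_radius: float = 25.0
    bilayer_thickness: float = 5.0
    area_per_lipid: float = 0.65

    def __post_init__(self) -> None:
        if not self.bilayer_thickness > 0:
            raise InvalidParameterError("bilayer_thickness must be > 0 nm")
        if not self.outer_radius > self.bilayer_thickness:
            raise InvalidParameterError(
                "outer_radius must exceed bilayer_thickness "
                f"(got {self.outer_radius} nm vs {self.bilayer_thickness} nm)"
            )
        if not self.area_per_lipid > 0:
            raise InvalidParameterError("area_per_lipid must be > 0 nm²")

    @property
    def inner_radius(self) -> float:
        return self.outer_radius - self.bilayer_thickness

    @property
    def outer_area_nm2(self) -> float:
        return 4.0 * math.pi * self.outer_radius**2


def thermal_energy(medium: Medium) -> float:
    """kB·T of the medium in joules (4.11e-21 J at 298.15 K)."""
    return medium.thermal_energy_j


def joules_to_kbt(energy_j: float, medium: Medium) -> float:
    return energy_j / medium.thermal_energy_j


def kbt_to_joules(energy_kbt: float, medium: Medium) -> float:
    return energy_kbt * medium.thermal_energy_j


def kbt_to_pn_nm(energy_kbt: float, medium: Medium) -> float:
    """1 kBT = 4.1146 pN·nm at 298.15 K."""
    return energy_kbt * medium.thermal_energy_j * 1e21


def pn_nm_to_kbt(energy_pn_nm: float, medium: Medium) -> float:
    return energy_pn_nm * 1e-21 / medium.thermal_energy_j


def lipids_per_vesicle(geom: VesicleGeometry) -> int:
    """Lipid copy number of one vesicle from its two spherical leaflets.

    (4π·R_outer² + 4π·R_inner²) / area_per_lipid, rounded to the nearest
    integer. For the default 25 nm / 5 nm / 0.65 nm² geometry this is
    ≈ 19,800 lipids.
    """
    area = 4.0 * math.pi * (geom.outer_radius**2 + geom.inner_radius**2)
    count = area / geom.area_per_lipid
    return int(round(count))


def vesicle_number_density(
    total_lipid_concentration_mol_per_l: float,
    mole_fraction: float,
    geom: VesicleGeometry,
) -> float:
    """Vesicle number density (per m³) from total lipid molarity.

    ``mole_fraction`` is the fraction of total lipid residing in the
    vesicle population of interest (e.g. 0.9 for tSUVs in a 9:1 t:v mix).
    """
    if not 0.0 <= mole_fraction <= 1.0:
        raise InvalidParameterError(
            f"mole_fraction must be within [0, 1], got {mole_fraction}"
        )
    if total_lipid_concentration_mol_per_l < 0:
        raise InvalidParameterError("lipid concentration must be >= 0")
    per_liter = (
        total_lipid_concentration_mol_per_l
        * mole_fraction
        * AVOGADRO_PER_MOL
        / lipids_per_vesicle(geom)
    )
    return per_liter * 1e3  # L⁻¹ → m⁻³
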