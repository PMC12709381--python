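"""Solution composition, Debye screening and related electrolyte utilities.

The experiments this package models are performed in aqueous solutions whose
composition is specified gravimetrically, i.e. in molality (mol solute per kg
of water).  All screening-related quantities, however, are functions of molar
concentration, so the conversion between the two scales (and the volume model
behind it) lives here, together with the ionic strength, Debye length,
relative permittivity, thermal-voltage and ideal osmotic-pressure helpers.

Zwitterions (``valence == 0``) are first-class citizens: they contribute to
osmotic pressure and, optionally, to the solution permittivity through a
linear dielectric increment, but never to the ionic strength.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import yaml
from pydantic import BaseModel, Field, model_validator

from .constants import (
    AVOGADRO,
    BOLTZMANN,
    DEFAULT_TEMPERATURE,
    ELEMENTARY_CHARGE,
    GAS_CONSTANT,
    VACUUM_PERMITTIVITY,
    WATER_RELATIVE_PERMITTIVITY,
    water_density,
)

__all__ = [
    "SpeciesSpec",
    "SolutionSpec",
    "ZeroIonicStrengthError",
    "molal_to_molar",
    "ionic_strength",
    "relative_permittivity",
    "debye_length",
    "ionic_strength_from_kappa",
    "thermal_voltage",
    "potential_in_thermal_units",
    "osmotic_pressure_vant_hoff",
    "proline",
    "potassium_chloride",
    "aqueous",
]


class ZeroIonicStrengthError(ValueError):
    """Raised when a screening length is requested for an ion-free solution.

    A solution of only neutral species has no predicted screening length;
    the inverse Debye length must then be treated as a free fit parameter.
    """


class SpeciesSpec(BaseModel, frozen=True):
    """One dissolved species.

    Parameters
    ----------
    molality : mol per kg of water, >= 0.
    valence : signed integer charge number; 0 for zwitterions.
    molar_mass : g/mol.
    dielectric_increment : linear permittivity shift per mol/L, default 0.
    partial_molar_volume : cm^3/mol, used by the solution volume model when
        provided; otherwise the species is assumed to add no volume.
    """

    name: str
    molality: float = Field(ge=0.0)
    valence: int = 0
    molar_mass: float = Field(gt=0.0)
    dielectric_increment: float = 0.0
    partial_molar_volume: float | None = None


class SolutionSpec(BaseModel, frozen=True):
    """An aqueous solution: species list, temperature and permittivity base."""

    species: tuple[SpeciesSpec, ...]
    temperature: float = DEFAULT_TEMPERATURE
    base_relative_permittivity: float = WATER_RELATIVE_PERMITTIVITY

    @model_validator(mode="after")
    def _check(self) -> "SolutionSpec":
        if not 273.0 <= self.temperature <= 373.0:
            raise ValueError(
                f"temperature {self.temperature} K outside the supported 273-373 K range"
            )
        if self.base_relative_permittivity <= 1.0:
            raise ValueError("base relative permittivity must exceed 1")
        net = sum(s.valence * s.molality for s in self.species)
        gross = sum(abs(s.valence) * s.molality for s in self.species)
        if gross > 0 and abs(net) > 1e-9 * max(gross, 1.0):
            raise ValueError(f"solution is not electroneutral: sum z*m = {net:g}")
        return self

    # -- serialization ---------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        """Write the solution as a key-value text (YAML) file.

        Units are fixed: molality in mol/kg, temperature in K,
        partial molar volume in cm^3/mol, dielectric increment per mol/L.
        """
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))

    @classmethod
    def from_file(cls, path: str | Path) -> "SolutionSpec":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()))


def _solution_volume_l_per_kg_water(spec: SolutionSpec) -> float:
    """Litres of solution per kg of water under the configured volume model.

    Default model: the solution volume is the volume of the water alone at
    the pure-water density; species carrying a ``partial_molar_volume`` add
    ``n * Vbar`` on top.
    """
    volume = 1.0 / water_density(spec.temperature)
    for s in spec.species:
        if s.partial_molar_volume is not None:
            volume += s.molality * s.partial_molar_volume / 1000.0
    return volume


def molal_to_molar(spec: SolutionSpec) -> dict[str, float]:
    """Per-species molar concentration (mol/L) from the molality scale."""
    volume = _solution_volume_l_per_kg_water(spec)
    return {s.name: s.molality / volume for s in spec.species}


def ionic_strength(spec: SolutionSpec) -> float:
    """Ionic strength I = 1/2 sum c_i z_i^2 in mol/L; zwitterions contribute 0."""
    molar = molal_to_molar(spec)
    return 0.5 * sum(molar[s.name] * s.valence**2 for s in spec.species)


def relative_permittivity(spec: SolutionSpec) -> float:
    """Solution relative permittivity: base + linear dielectric increments."""
    molar = molal_to_molar(spec)
    eps = spec.base_relative_permittivity + sum(
        s.dielectric_increment * molar[s.name] for s in spec.species
    )
    if eps <= 1.0:
        raise ValueError(f"relative permittivity {eps:g} <= 1 is unphysical")
    return eps


def debye_length(spec: SolutionSpec) -> float:
    """Debye screening length kappa^-1 in metres.

    kappa^-1 = sqrt(eps0 eps_e kB T / (2 NA e^2 I)) with I converted to
    mol/m^3.  Raises :class:`ZeroIonicStrengthError` for ion-free solutions.
    """
    strength = ionic_strength(spec)
    if strength <= 0.0:
        raise ZeroIonicStrengthError(
            "no predicted screening length: solution has zero ionic strength; "
            "treat kappa as a free fit parameter"
        )
    eps_e = relative_permittivity(spec)
    return _kappa_inv(strength, spec.temperature, eps_e)


def _kappa_inv(strength_molar: float, temperature: float, eps_e: float) -> float:
    i_si = strength_molar * 1000.0 * AVOGADRO  # ions per m^3 (number density scale)
    return math.sqrt(
        VACUUM_PERMITTIVITY * eps_e * BOLTZMANN * temperature
        / (2.0 * ELEMENTARY_CHARGE**2 * i_si)
    )


def ionic_strength_from_kappa(
    kappa_inv: float,
    temperature: float = DEFAULT_TEMPERATURE,
    eps_e: float = WATER_RELATIVE_PERMITTIVITY,
) -> float:
    """Exact algebraic inverse of :func:`debye_length`, returning mol/L.

    Useful for inferring the free-ion content of a nominally pure solution
    from its measured screening length.
    """
    if kappa_inv <= 0:
        raise ValueError("kappa_inv must be positive")
    i_si = (
        VACUUM_PERMITTIVITY * eps_e * BOLTZMANN * temperature
        / (2.0 * ELEMENTARY_CHARGE**2 * kappa_inv**2)
    )
    return i_si / (1000.0 * AVOGADRO)


def thermal_voltage(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """kB T / e in volts (25.7 mV at 298.15 K)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return BOLTZMANN * temperature / ELEMENTARY_CHARGE


def potential_in_thermal_units(psi: float, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Potential expressed in units of kB T / e."""
    return psi / thermal_voltage(temperature)


def osmotic_pressure_vant_hoff(spec: SolutionSpec) -> float:
    """Ideal-dilute (van't Hoff) osmotic pressure, Pa.

    Pi = R T sum c_i over all dissolved species: each ion counts once,
    a zwitterion counts once.  No activity corrections.
    """
    total = sum(molal_to_molar(spec).values())  # mol/L
    return GAS_CONSTANT * spec.temperature * total * 1000.0


# -- convenience constructors -------------------------------------------

#: Molar masses, g/mol.
_MM_K = 39.0983
_MM_CL = 35.453
_MM_PROLINE = 115.131


def proline(molality: float, dielectric_increment: float = 0.0,
            partial_molar_volume: float | None = None) -> SpeciesSpec:
    """L-proline as a net-neutral zwitterion (between its two pKa values)."""
    return SpeciesSpec(
        name="proline",
        molality=molality,
        valence=0,
        molar_mass=_MM_PROLINE,
        dielectric_increment=dielectric_increment,
        partial_molar_volume=partial_molar_volume,
    )


def potassium_chloride(molality: float) -> tuple[SpeciesSpec, SpeciesSpec]:
    """Fully dissociated KCl as a (K+, Cl-) species pair."""
    return (
        SpeciesSpec(name="K+", molality=molality, valence=1, molar_mass=_MM_K),
        SpeciesSpec(name="Cl-", molality=molality, valence=-1, molar_mass=_MM_CL),
    )


def aqueous(
    proline_molal: float = 0.0,
    kcl_molal: float = 0.0,
    temperature: float = DEFAULT_TEMPERATURE,
    extra: Iterable[SpeciesSpec] = (),
) -> SolutionSpec:
    """Build a proline/KCl solution, the composition family studied here."""
    species: list[SpeciesSpec] = []
    if proline_molal > 0:
        species.append(proline(proline_molal))
    if kcl_molal > 0:
        species.extend(potassium_chloride(kcl_molal))
    species.extend(extra)
    return SolutionSpec(species=tuple(species), temperature=temperature)
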