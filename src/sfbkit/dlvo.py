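"""Charge-regulated DLVO interaction free energy between flat plates.

The model is the sum of a non-retarded van der Waals attraction and a
weak-overlap electric double-layer repulsion with the *constant regulation*
closure::

    W(D) = -A / (12 pi D^2)
           + 2 eps0 eps_e kappa psi_eff^2 exp(-kappa D)
             / (1 + (1 - 2 p) exp(-kappa D))

``p`` interpolates linearly between the constant-potential (p = 0) and
constant-charge (p = 1) boundary conditions; ``psi_eff`` is the effective
(diffuse-layer) surface potential of the isolated surface, stored as a
magnitude.  Repulsion is positive; energies are per unit area (J/m^2).

Also provided: the Grahame relation between surface potential and diffuse
charge density, and the Derjaguin conversion between plate energy and
crossed-cylinder/sphere force, F = 2 pi R W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, Field

from . import electrolyte
from .constants import (
    BOLTZMANN,
    DEFAULT_HAMAKER,
    E_PER_NM2,
    ELEMENTARY_CHARGE,
    VACUUM_PERMITTIVITY,
)

__all__ = [
    "DlvoParams",
    "EnergyProfile",
    "RegulationDivergenceError",
    "vdw_energy",
    "edl_energy",
    "total_energy",
    "total_energy_gradient",
    "grahame_sigma",
    "sigma_in_e_per_nm2",
    "energy_to_force",
    "force_to_energy",
]

#: Evaluation refuses separations where the regulation denominator is below
#: this value instead of returning huge numbers.
DENOMINATOR_GUARD = 1e-6


class RegulationDivergenceError(ValueError):
    """The constant-regulation denominator vanished (p near 1, kappa*D -> 0)."""


class DlvoParams(BaseModel, frozen=True):
    """Parameter vector of the interaction model.

    ``psi_eff`` (V) is a sign-free magnitude, ``kappa`` (1/m) the inverse
    screening length, ``p`` in [0, 1] the regulation parameter and
    ``hamaker`` (J) the Hamaker constant (> 0 means attractive).
    """

    psi_eff: float = Field(ge=0.0)
    kappa: float = Field(gt=0.0)
    p: float = Field(ge=0.0, le=1.0)
    hamaker: float = Field(default=DEFAULT_HAMAKER, ge=0.0)

    @property
    def kappa_inv(self) -> float:
        """Screening length in metres."""
        return 1.0 / self.kappa


@dataclass
class EnergyProfile:
    """W(D) sampled on a strictly increasing separation grid (SI units)."""

    separations: np.ndarray  # m, strictly increasing, > 0
    energy: np.ndarray  # J/m^2, repulsion positive

    def __post_init__(self) -> None:
        self.separations = np.asarray(self.separations, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        if self.separations.shape != self.energy.shape:
            raise ValueError("separations and energy must have the same length")
        if self.separations.size and (
            np.any(self.separations <= 0) or np.any(np.diff(self.separations) <= 0)
        ):
            raise ValueError("separations must be strictly increasing and positive")


def _check_positive_d(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("separation D must be positive")
    return d


def vdw_energy(d, hamaker: float = DEFAULT_HAMAKER):
    """Non-retarded van der Waals plate-plate energy, -A / (12 pi D^2)."""
    d = _check_positive_d(d)
    if hamaker < 0:
        raise ValueError("hamaker must be >= 0")
    return -hamaker / (12.0 * np.pi * d**2)


def edl_energy(d, params: DlvoParams, eps_e: float):
    """Constant-regulation electric double-layer energy, J/m^2 (>= 0)."""
    d = _check_positive_d(d)
    decay = np.exp(-params.kappa * d)
    denom = 1.0 + (1.0 - 2.0 * params.p) * decay
    if np.any(denom < DENOMINATOR_GUARD):
        raise RegulationDivergenceError(
            "regulation denominator below guard; restrict the separation window"
        )
    prefactor = 2.0 * VACUUM_PERMITTIVITY * eps_e * params.kappa * params.psi_eff**2
    return prefactor * decay / denom


def total_energy(d, params: DlvoParams, eps_e: float):
    """Total interaction free energy: van der Waals plus double layer."""
    return vdw_energy(d, params.hamaker) + edl_energy(d, params, eps_e)


def total_energy_gradient(d, params: DlvoParams, eps_e: float):
    """dW/dD of the total energy (analytic), used by the mechanics simulator.

    The double-layer derivative takes the compact form
    ``dW_edl/dD = -kappa W_edl / (1 + (1-2p) exp(-kappa D))``.
    """
    d = _check_positive_d(d)
    decay = np.exp(-params.kappa * d)
    denom = 1.0 + (1.0 - 2.0 * params.p) * decay
    if np.any(denom < DENOMINATOR_GUARD):
        raise RegulationDivergenceError(
            "regulation denominator below guard; restrict the separation window"
        )
    w_edl = (
        2.0 * VACUUM_PERMITTIVITY * eps_e * params.kappa * params.psi_eff**2 * decay / denom
    )
    return params.hamaker / (6.0 * np.pi * d**3) - params.kappa * w_edl / denom


def _is_one_to_one(spec: electrolyte.SolutionSpec) -> bool:
    charged = [s for s in spec.species if s.valence != 0 and s.molality > 0]
    return bool(charged) and all(abs(s.valence) == 1 for s in charged)


def grahame_sigma(psi: float, spec: electrolyte.SolutionSpec, variant: str = "full") -> float:
    """Diffuse-layer surface charge density (C/m^2) from the surface potential.

    ``variant="full"`` uses the nonlinear Grahame relation for a 1:1
    electrolyte, ``sigma = (2 eps0 eps_e kappa kB T / e) sinh(e psi / 2 kB T)``;
    ``variant="linearized"`` uses the Debye-Huckel limit
    ``sigma = eps0 eps_e kappa psi``.  Requires nonzero ionic strength.
    """
    kappa_inv = electrolyte.debye_length(spec)  # raises on zero ionic strength
    eps_e = electrolyte.relative_permittivity(spec)
    kappa = 1.0 / kappa_inv
    if variant == "linearized":
        return VACUUM_PERMITTIVITY * eps_e * kappa * psi
    if variant == "full":
        if not _is_one_to_one(spec):
            raise ValueError("full Grahame variant supports 1:1 electrolytes only")
        vt = BOLTZMANN * spec.temperature / ELEMENTARY_CHARGE
        return 2.0 * VACUUM_PERMITTIVITY * eps_e * kappa * vt * np.sinh(psi / (2.0 * vt))
    raise ValueError(f"unknown Grahame variant {variant!r}")


def sigma_in_e_per_nm2(sigma: float) -> float:
    """Convert a charge density from C/m^2 to elementary charges per nm^2."""
    return sigma / E_PER_NM2


def energy_to_force(w, radius: float):
    """Derjaguin relation: crossed-cylinder force F = 2 pi R W."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return 2.0 * np.pi * radius * np.asarray(w, dtype=float)


def force_to_energy(f, radius: float):
    """Inverse Derjaguin relation: W = F / (2 pi R)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    return np.asarray(f, dtype=float) / (2.0 * np.pi * radius)
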