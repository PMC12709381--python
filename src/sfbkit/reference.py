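"""Reference DLVO parameter sets for mica across proline/KCl solutions.

These are the fitted effective surface potentials, screening lengths and
regulation parameters for the six solution compositions studied with the
surface force balance (pure water, three proline-only concentrations, a
proline/KCl mixture, and KCl alone), together with the short-range
phenomenology: the ~0.5 nm proline squeeze-out layer, the 0.3 nm hydration
step with salt, and the ~-1 mJ/m^2 pull-off energy.  They serve as ground
truths for synthetic-data generation and as targets for recovery scoring.
"""

from __future__ import annotations

from dataclasses import dataclass

from .constants import DEFAULT_HAMAKER
from .dlvo import DlvoParams
from .electrolyte import SolutionSpec, aqueous
from .simulate import GroundTruth, StructuralForceSpec

__all__ = [
    "ReferenceFit",
    "REFERENCE_FITS",
    "by_composition",
    "ground_truth",
    "solution",
    "PROLINE_LAYER_THICKNESS",
    "SALT_LAYER_THICKNESS",
    "PULL_OFF_ENERGY",
]

#: Squeeze-out step of a proline layer at high proline concentration, m.
PROLINE_LAYER_THICKNESS = 0.5e-9
#: Hydration-structure step with added KCl, m.
SALT_LAYER_THICKNESS = 0.3e-9
#: Pull-off (adhesion) energy needed to separate the surfaces from
#: contact in the low-concentration proline solution, J/m^2.
PULL_OFF_ENERGY = -1.0e-3


@dataclass(frozen=True)
class ReferenceFit:
    """One row of the reference parameter table (laboratory units)."""

    label: str
    c_pro_molal: float
    c_kcl_molal: float
    psi_eff_mV: float
    psi_eff_sd_mV: float
    kappa_inv_nm: float
    kappa_inv_sd_nm: float
    p: float
    p_sd: float
    kappa_pred_inv_nm: float | None  # None where no prediction exists

    def dlvo(self, hamaker: float = DEFAULT_HAMAKER) -> DlvoParams:
        return DlvoParams(
            psi_eff=self.psi_eff_mV * 1e-3,
            kappa=1.0 / (self.kappa_inv_nm * 1e-9),
            p=self.p,
            hamaker=hamaker,
        )


REFERENCE_FITS: tuple[ReferenceFit, ...] = (
    ReferenceFit("water", 0.0, 0.0, 38.0, 12.0, 65.0, 21.0, 0.88, 0.10, None),
    ReferenceFit("pro-0.07m", 0.07, 0.0, 63.0, 5.0, 40.0, 2.0, 0.90, 0.01, None),
    ReferenceFit("pro-0.35m", 0.35, 0.0, 55.0, 2.0, 34.0, 7.0, 0.92, 0.02, None),
    ReferenceFit("pro-0.90m", 0.90, 0.0, 49.0, 2.0, 30.0, 5.0, 0.92, 0.03, None),
    ReferenceFit("pro-0.46m+kcl-0.01m", 0.46, 0.01, 49.0, 3.0, 3.0, 0.2, 0.61, 0.08, 3.34),
    ReferenceFit("kcl-0.01m", 0.0, 0.01, 29.0, 1.0, 3.8, 0.8, 1.0, 0.0, 3.1),
)


def by_composition(c_pro_molal: float, c_kcl_molal: float) -> ReferenceFit:
    """Look up the reference row for a given solution composition."""
    for row in REFERENCE_FITS:
        if row.c_pro_molal == c_pro_molal and row.c_kcl_molal == c_kcl_molal:
            return row
    raise KeyError(f"no reference fit for c_Pro={c_pro_molal} m, c_KCl={c_kcl_molal} m")


def solution(row: ReferenceFit) -> SolutionSpec:
    """The solution composition behind a reference row."""
    return aqueous(proline_molal=row.c_pro_molal, kcl_molal=row.c_kcl_molal)


def ground_truth(
    row: ReferenceFit,
    hamaker: float = DEFAULT_HAMAKER,
    structural: StructuralForceSpec | None = None,
    adhesion_minimum: float | None = None,
) -> GroundTruth:
    """Build a simulator ground truth from a reference row."""
    return GroundTruth(
        dlvo=row.dlvo(hamaker),
        structural=structural,
        adhesion_minimum=adhesion_minimum,
    )
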