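"""Physical constants and small numeric helpers shared across the package.

All constants are CODATA values re-exported from :mod:`scipy.constants`;
nothing here is fitted or tunable.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

from scipy.constants import Avogadro as AVOGADRO
from scipy.constants import Boltzmann as BOLTZMANN
from scipy.constants import elementary_charge as ELEMENTARY_CHARGE
from scipy.constants import epsilon_0 as VACUUM_PERMITTIVITY

#: Molar gas constant, J/(mol K).
GAS_CONSTANT = BOLTZMANN * AVOGADRO

#: Relative permittivity of pure water at 298.15 K (dimensionless).
WATER_RELATIVE_PERMITTIVITY = 78.3

#: Default laboratory temperature, K.
DEFAULT_TEMPERATURE = 298.15

#: 1 e/nm^2 expressed in C/m^2 (fixed by the CODATA elementary charge).
E_PER_NM2 = ELEMENTARY_CHARGE * 1e18

#: Literature Hamaker constant for mica-water-mica, J.  Configurable
#: everywhere it is used; this is only a default.
DEFAULT_HAMAKER = 2.2e-20


def water_density(temperature: float) -> float:
    """Density of air-free pure water, kg/L, Kell's (1975) correlation.

    Valid for 273.15 K <= ``temperature`` <= 423.15 K; accurate to a few
    ppm over the range used here (0-100 C).
    """
    t = temperature - 273.15
    if not -0.1 <= t <= 150.0:
        raise ValueError(f"water_density: temperature {temperature} K outside 273-423 K")
    num = (
        999.83952
        + 16.945176 * t
        - 7.9870401e-3 * t**2
        - 46.170461e-6 * t**3
        + 105.56302e-9 * t**4
        - 280.54253e-12 * t**5
    )
    return num / (1.0 + 16.879850e-3 * t) / 1000.0  # g/cm^3 -> kg/L


def round_sig(value: float, n_digits: int = 2) -> float:
    """Round ``value`` to ``n_digits`` significant figures, half away from zero.

    This is the reporting convention used for parameter tables: 3.04 -> 3.0,
    3.05 -> 3.1, 0.897 -> 0.90 at two significant figures.
    """
    if value == 0 or not _isfinite(value):
        return value
    d = Decimal(repr(float(value)))
    quantum = Decimal(1).scaleb(d.adjusted() - (n_digits - 1))
    return float(d.quantize(quantum, rounding=ROUND_HALF_UP))


def _isfinite(x: float) -> bool:
    return x == x and x not in (float("inf"), float("-inf"))
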