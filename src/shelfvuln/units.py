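"""Dissolved-oxygen unit conversions and seawater oxygen solubility.

Literature thresholds arrive in a zoo of units (mg/L, mL/L, µmol/L, µmol/kg,
percent saturation); the vulnerability analysis works throughout in mg/L.
Conversions touching percent saturation or per-kilogram units require the
water conditions (temperature, salinity, pressure), mirroring the fact that
saturation concentration and density are state-dependent.

Solubility uses the Garcia & Gordon (1992) refit of the Benson & Krause
data — the same fit behind the USGS online oxygen-solubility tables — and
seawater density at surface pressure uses the UNESCO EOS-80 polynomial.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

__all__ = [
    "OxygenUnit",
    "OxygenQuantity",
    "WaterConditions",
    "DomainError",
    "MissingConditionsError",
    "O2_MOLAR_MASS",
    "MG_PER_ML",
    "solubility",
    "density",
    "convert",
    "solubility_reduction_pct",
]

#: Molar mass of O2, g/mol.
O2_MOLAR_MASS = 31.9988

#: mg of O2 per mL of O2 gas: molar mass / real-gas molar volume at STP
#: (31.9988 g/mol / 22.392 L/mol).
MG_PER_ML = 1.42905

#: Partial molar volume of O2 in seawater, m^3/mol (Taylor 1978), used only
#: for the in-situ hydrostatic solubility correction; at the default surface
#: pressure the correction is exactly 1.
_O2_PARTIAL_MOLAR_VOLUME = 32.0e-6
_GAS_CONSTANT = 8.31446  # J / (mol K)


class DomainError(ValueError):
    """Water conditions outside the validity range of the fits."""


class MissingConditionsError(ValueError):
    """A state-dependent conversion was requested without water conditions."""


class OxygenUnit(str, Enum):
    MG_PER_L = "mg_per_L"
    UMOL_PER_L = "umol_per_L"
    ML_PER_L = "ml_per_L"
    PERCENT_SATURATION = "percent_saturation"
    UMOL_PER_KG = "umol_per_kg"


@dataclass(frozen=True)
class WaterConditions:
    """Temperature (°C, ITS-90), practical salinity, pressure (dbar).

    Pressure defaults to 0 dbar (sea surface), the assumption used when
    converting literature values reported without pressure information.
    """

    temperature: float
    salinity: float
    pressure: float = 0.0

    def __post_init__(self) -> None:
        if not (-2.0 <= self.temperature <= 40.0):
            raise DomainError(
                f"temperature {self.temperature} °C outside [-2, 40]"
            )
        if not (0.0 <= self.salinity <= 42.0):
            raise DomainError(f"salinity {self.salinity} outside [0, 42]")
        if self.pressure < 0.0:
            raise DomainError(f"pressure {self.pressure} dbar must be >= 0")


@dataclass(frozen=True)
class OxygenQuantity:
    """An oxygen concentration (or signed anomaly/trend) with its unit."""

    value: float
    unit: OxygenUnit

    def __post_init__(self) -> None:
        if not math.isfinite(self.value):
            raise ValueError("oxygen value must be finite")
        object.__setattr__(self, "unit", OxygenUnit(self.unit))


# Garcia & Gordon (1992) solubility fit to the Benson & Krause data,
# volumetric coefficient set (result in mL/L).  Valid 0-40 °C, 0-42 salinity.
_GG_A = (2.00907, 3.22014, 4.05010, 4.94457, -2.56847e-1, 3.88767)
_GG_B = (-6.24523e-3, -7.37614e-3, -1.03410e-2, -8.17083e-3)
_GG_C0 = -4.88682e-7


def _scaled_temperature(t: float) -> float:
    return math.log((298.15 - t) / (273.15 + t))


def solubility(conditions: WaterConditions) -> float:
    """Oxygen saturation concentration in mg/L at the given conditions.

    Benson–Krause fit (Garcia & Gordon 1992 coefficients) evaluated at one
    standard atmosphere of moist air; a nonzero hydrostatic pressure applies
    the exponential partial-molar-volume correction. Strictly decreasing in
    both temperature and salinity over the valid domain.
    """
    ts = _scaled_temperature(conditions.temperature)
    ln_c = _GG_C0 * conditions.salinity**2
    ln_c += sum(a * ts**i for i, a in enumerate(_GG_A))
    ln_c += conditions.salinity * sum(b * ts**i for i, b in enumerate(_GG_B))
    ml_per_l = math.exp(ln_c)
    if conditions.pressure > 0.0:
        t_kelvin = conditions.temperature + 273.15
        pascals = conditions.pressure * 1.0e4  # 1 dbar = 10^4 Pa
        ml_per_l *= math.exp(
            _O2_PARTIAL_MOLAR_VOLUME * pascals / (_GAS_CONSTANT * t_kelvin)
        )
    return ml_per_l * MG_PER_ML


def density(conditions: WaterConditions) -> float:
    """Seawater density in kg/m³ at surface pressure (UNESCO EOS-80)."""
    t = conditions.temperature
    s = conditions.salinity
    rho_w = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        8.24493e-1
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    return rho_w + a * s + b * s**1.5 + 4.8314e-4 * s**2


def _to_mg_per_l(q: OxygenQuantity, conditions: WaterConditions | None) -> float:
    if q.unit is OxygenUnit.MG_PER_L:
        return q.value
    if q.unit is OxygenUnit.UMOL_PER_L:
        return q.value * O2_MOLAR_MASS / 1000.0
    if q.unit is OxygenUnit.ML_PER_L:
        return q.value * MG_PER_ML
    if conditions is None:
        raise MissingConditionsError(
            f"conversion from {q.unit.value} requires water conditions "
            "(temperature, salinity)"
        )
    if q.unit is OxygenUnit.UMOL_PER_KG:
        kg_per_l = density(conditions) / 1000.0
        return q.value * O2_MOLAR_MASS / 1000.0 * kg_per_l
    # percent saturation
    return q.value / 100.0 * solubility(conditions)


def _from_mg_per_l(
    mg_l: float, unit: OxygenUnit, conditions: WaterConditions | None
) -> float:
    if unit is OxygenUnit.MG_PER_L:
        return mg_l
    if unit is OxygenUnit.UMOL_PER_L:
        return mg_l * 1000.0 / O2_MOLAR_MASS
    if unit is OxygenUnit.ML_PER_L:
        return mg_l / MG_PER_ML
    if conditions is None:
        raise MissingConditionsError(
            f"conversion to {unit.value} requires water conditions "
            "(temperature, salinity)"
        )
    if unit is OxygenUnit.UMOL_PER_KG:
        kg_per_l = density(conditions) / 1000.0
        return mg_l * 1000.0 / O2_MOLAR_MASS / kg_per_l
    return mg_l / solubility(conditions) * 100.0


def convert(
    q: OxygenQuantity,
    to_unit: OxygenUnit | str,
    conditions: WaterConditions | None = None,
) -> OxygenQuantity:
    """Convert an oxygen quantity between units, pivoting through mg/L.

    Signed values (anomalies, trends) convert like concentrations. Raises
    :class:`MissingConditionsError` when a percent-saturation or per-kg
    conversion is attempted without conditions.
    """
    to_unit = OxygenUnit(to_unit)
    mg_l = _to_mg_per_l(q, conditions)
    return OxygenQuantity(_from_mg_per_l(mg_l, to_unit, conditions), to_unit)


def solubility_reduction_pct(
    baseline: WaterConditions, dT: float, dS: float
) -> float:
    """Percent loss of oxygen solubility under a (ΔT, ΔS) perturbation.

    100 × (1 − C*(T+ΔT, S+ΔS) / C*(T, S)); positive for warming and/or
    salinification. Used to derive the solubility-driven component of future
    deoxygenation scenarios.
    """
    perturbed = WaterConditions(
        baseline.temperature + dT, baseline.salinity + dS, baseline.pressure
    )
    return 100.0 * (1.0 - solubility(perturbed) / solubility(baseline))
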