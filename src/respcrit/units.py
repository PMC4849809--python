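"""Dissolved-oxygen solubility and unit conversion.

Published critical-oxygen-level (Pcrit) values appear in five different
oxygen units (kPa, mmHg/torr, % air saturation, mg/L, umol/L).  Comparing
them requires a common currency: the partial pressure of oxygen in kPa,
reachable from any of the others given water temperature, salinity and
barometric pressure.  This module provides the solubility model and the
conversions, plus the small pressure-unit helpers (uatm/atm/mmHg/kPa) used
by the carbonate-chemistry model.

Solubility is the Garcia & Gordon (1992) fit to the Benson & Krause data,
evaluated in umol/kg and densified to per-litre concentrations with the
one-atmosphere seawater equation of state (Millero & Poisson 1981).  Water
vapour pressure follows Benson & Krause; the dry-air O2 mole fraction is
fixed at 0.20946.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "OXYGEN_UNITS",
    "PRESSURE_UNITS",
    "O2_MOLAR_MASS",
    "WaterConditions",
    "OxygenQuantity",
    "water_vapour_pressure",
    "po2_air_saturation",
    "o2_solubility",
    "convert_o2",
    "pressure_unit",
]

#: grams of O2 per mole (31.998 g/mol)
O2_MOLAR_MASS = 31.998

#: mole fraction of O2 in dry air
O2_MOLE_FRACTION = 0.20946

KPA_PER_ATM = 101.325
MMHG_PER_ATM = 760.0

OXYGEN_UNITS = frozenset(
    {"kPa", "mmHg", "torr", "percent_air_saturation", "mg_per_L", "umol_per_L"}
)

#: conversion factors to atmospheres
PRESSURE_UNITS = {
    "atm": 1.0,
    "uatm": 1e-6,
    "mmHg": 1.0 / MMHG_PER_ATM,
    "kPa": 1.0 / KPA_PER_ATM,
}

_PRESSURE_FAMILY = {"kPa", "mmHg", "torr"}
_CONCENTRATION_FAMILY = {"mg_per_L", "umol_per_L"}


class DomainError(ValueError):
    """An input lies outside the validity domain of the formulations."""


@dataclass(frozen=True)
class WaterConditions:
    """Water temperature, salinity and barometric pressure.

    Parameters
    ----------
    temperature : float
        Water temperature, degrees Celsius.  Valid range -2 to 40.
    salinity : float
        Practical salinity (PSU).  Valid range 0 to 100.
    barometric_pressure : float
        Station pressure in mmHg; defaults to standard sea-level
        pressure (760 mmHg), the assumption applied to literature values
        that do not report pressure.
    """

    temperature: float
    salinity: float = 0.0
    barometric_pressure: float = 760.0

    def __post_init__(self) -> None:
        if not -2.0 <= self.temperature <= 40.0:
            raise DomainError(
                f"temperature {self.temperature} degC outside valid range [-2, 40]"
            )
        if not 0.0 <= self.salinity <= 100.0:
            raise DomainError(
                f"salinity {self.salinity} PSU outside valid range [0, 100]"
            )
        if not 400.0 <= self.barometric_pressure <= 800.0:
            raise DomainError(
                f"barometric_pressure {self.barometric_pressure} mmHg outside "
                "valid range [400, 800]"
            )


@dataclass(frozen=True)
class OxygenQuantity:
    """A dissolved-oxygen amount tagged with its unit."""

    value: float
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in OXYGEN_UNITS:
            raise ValueError(
                f"unknown oxygen unit {self.unit!r}; expected one of {sorted(OXYGEN_UNITS)}"
            )
        if self.value < 0:
            raise ValueError(f"oxygen value must be >= 0, got {self.value}")


def water_vapour_pressure(temperature: float) -> float:
    """Saturation water vapour pressure in kPa (Benson & Krause formula).

    Salinity lowers vapour pressure by <0.1% over oceanic salinities and
    is ignored, as is standard respirometry practice.
    """
    tk = temperature + 273.15
    return math.exp(11.8571 - 3840.70 / tk - 216961.0 / tk**2) * KPA_PER_ATM


def po2_air_saturation(conditions: WaterConditions) -> float:
    """PO2 (kPa) of water equilibrated with humid air at the given conditions."""
    baro_kpa = conditions.barometric_pressure * KPA_PER_ATM / MMHG_PER_ATM
    return O2_MOLE_FRACTION * (baro_kpa - water_vapour_pressure(conditions.temperature))


def _gg_umol_per_kg(temperature: float, salinity: float) -> float:
    # Garcia & Gordon (1992) combined fit to Benson & Krause, umol/kg at
    # one atmosphere of water-saturated air.
    ts = math.log((298.15 - temperature) / (273.15 + temperature))
    a = (5.80871, 3.20291, 4.17887, 5.10006, -9.86643e-2, 3.80369)
    b = (-7.01577e-3, -7.70028e-3, -1.13864e-2, -9.51519e-3)
    c0 = -2.75915e-7
    ln_c = (
        sum(ai * ts**i for i, ai in enumerate(a))
        + salinity * sum(bi * ts**i for i, bi in enumerate(b))
        + c0 * salinity**2
    )
    return math.exp(ln_c)


def seawater_density(temperature: float, salinity: float) -> float:
    """Surface seawater density in kg/L (Millero & Poisson 1981)."""
    t = temperature
    rho0 = (
        999.842594
        + 6.793952e-2 * t
        - 9.095290e-3 * t**2
        + 1.001685e-4 * t**3
        - 1.120083e-6 * t**4
        + 6.536332e-9 * t**5
    )
    a = (
        0.824493
        - 4.0899e-3 * t
        + 7.6438e-5 * t**2
        - 8.2467e-7 * t**3
        + 5.3875e-9 * t**4
    )
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return (rho0 + a * salinity + b * salinity**1.5 + c * salinity**2) / 1000.0


def o2_solubility(conditions: WaterConditions) -> tuple[float, float]:
    """Air-saturated O2 concentration and per-kPa solubility coefficient.

    Returns
    -------
    c_sat : float
        Air-saturated dissolved O2 in mg/L at the given barometric pressure.
    beta : float
        Solubility coefficient in mg/L per kPa of PO2, i.e.
        ``c_sat / po2_air_saturation``.

    Notes
    -----
    The pressure correction scales the one-atmosphere saturation value by
    the ratio of dry-gas pressures ``(P - pw) / (P0 - pw)``.
    """
    umol_kg = _gg_umol_per_kg(conditions.temperature, conditions.salinity)
    rho = seawater_density(conditions.temperature, conditions.salinity)
    c_sat_1atm = umol_kg * rho * O2_MOLAR_MASS * 1e-3
    pw = water_vapour_pressure(conditions.temperature)
    baro_kpa = conditions.barometric_pressure * KPA_PER_ATM / MMHG_PER_ATM
    c_sat = c_sat_1atm * (baro_kpa - pw) / (KPA_PER_ATM - pw)
    beta = c_sat / po2_air_saturation(conditions)
    return c_sat, beta


def _to_kpa(q: OxygenQuantity, conditions: WaterConditions | None) -> float:
    unit, v = q.unit, q.value
    if unit == "kPa":
        return v
    if unit in ("mmHg", "torr"):
        return v * KPA_PER_ATM / MMHG_PER_ATM
    if conditions is None:
        raise ValueError(
            f"converting from {unit!r} requires WaterConditions (temperature, "
            "salinity, barometric pressure)"
        )
    if unit == "percent_air_saturation":
        return v / 100.0 * po2_air_saturation(conditions)
    _, beta = o2_solubility(conditions)
    if unit == "mg_per_L":
        return v / beta
    # umol_per_L
    return v * O2_MOLAR_MASS * 1e-3 / beta


def _from_kpa(kpa: float, unit: str, conditions: WaterConditions | None) -> float:
    if unit == "kPa":
        return kpa
    if unit in ("mmHg", "torr"):
        return kpa * MMHG_PER_ATM / KPA_PER_ATM
    if conditions is None:
        raise ValueError(
            f"converting to {unit!r} requires WaterConditions (temperature, "
            "salinity, barometric pressure)"
        )
    if unit == "percent_air_saturation":
        return kpa / po2_air_saturation(conditions) * 100.0
    _, beta = o2_solubility(conditions)
    if unit == "mg_per_L":
        return kpa * beta
    return kpa * beta / (O2_MOLAR_MASS * 1e-3)


def convert_o2(
    q: OxygenQuantity,
    target_unit: str,
    conditions: WaterConditions | None = None,
) -> OxygenQuantity:
    """Convert a dissolved-oxygen quantity between any two supported units.

    Pressure-family units (kPa, mmHg, torr) interconvert by exact factors
    (760 mmHg = 101.325 kPa; torr treated as identical to mmHg).  Any
    conversion touching % air saturation or a concentration requires
    ``conditions``.  Round trips reproduce the input to 1e-9 relative.
    """
    if target_unit not in OXYGEN_UNITS:
        raise ValueError(
            f"unknown target unit {target_unit!r}; expected one of {sorted(OXYGEN_UNITS)}"
        )
    if target_unit == q.unit:
        return OxygenQuantity(q.value, q.unit)
    if q.unit in _PRESSURE_FAMILY and target_unit in _PRESSURE_FAMILY:
        return OxygenQuantity(_from_kpa(_to_kpa(q, None), target_unit, None), target_unit)
    if q.unit == "mg_per_L" and target_unit == "umol_per_L":
        return OxygenQuantity(q.value / (O2_MOLAR_MASS * 1e-3), target_unit)
    if q.unit == "umol_per_L" and target_unit == "mg_per_L":
        return OxygenQuantity(q.value * O2_MOLAR_MASS * 1e-3, target_unit)
    kpa = _to_kpa(q, conditions)
    return OxygenQuantity(_from_kpa(kpa, target_unit, conditions), target_unit)


def pressure_unit(value: float, from_unit: str, to_unit: str) -> float:
    """Convert a pressure among uatm, atm, mmHg and kPa.

    Factors are chained through the exact identities
    1 atm = 1e6 uatm = 760 mmHg = 101.325 kPa.
    """
    for u in (from_unit, to_unit):
        if u not in PRESSURE_UNITS:
            raise ValueError(
                f"unknown pressure unit {u!r}; expected one of {sorted(PRESSURE_UNITS)}"
            )
    return value * PRESSURE_UNITS[from_unit] / PRESSURE_UNITS[to_unit]
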