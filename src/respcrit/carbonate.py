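"""Seawater carbonate chemistry on the NBS pH scale, and the
closed-respirometer CO2-accumulation model.

During a closed-chamber Pcrit trial the fish excretes CO2 while it depletes
O2.  The partial pressure of CO2 reached depends strongly on the starting
water chemistry: higher pH means higher total alkalinity (TA) and a greater
capacity to buffer added CO2.  The model here quantifies that: for each
(starting pH, salinity) cell it computes the initial TA and DIC from the pH
assuming equilibration with the atmosphere, adds the respired CO2 to DIC at
constant TA, and solves for the final pCO2.

Constant set (pinned; final pCO2 is sensitive to the choice):

* K0 (CO2 solubility): Weiss (1974), mol/kg/atm.
* K1, K2: Mehrbach et al. (1973) original fits — the carbonic-acid
  constants native to the NBS scale, as paired with NBS output in CO2SYS.
* KB: Lyman (1969), the boric-acid constant CO2SYS pairs with the
  Mehrbach-original/NBS choice.
* KW: Millero (1995), converted to NBS via fH.
* fH (NBS activity factor): Takahashi et al. (1982).
* Total borate: 410.6 * S/35 umol/kg (Culberson).

Hydrogen ion enters all equilibria as the NBS activity aH = 10**(-pH); the
free proton concentration used in the alkalinity balance is aH/fH.  The
"uM" of the respired-CO2 addition is treated as umol/kg (the per-litre
difference is <2%, far below the model's precision).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .units import WaterConditions, o2_solubility, po2_air_saturation, seawater_density

__all__ = [
    "EquilibriumConstants",
    "CarbonateState",
    "RespirometerCO2Scenario",
    "RespirometerCO2Result",
    "constants",
    "state_from_ph_pco2",
    "pco2_from_ta_dic",
    "respirometer_co2_model",
    "delta_dic_from_o2",
]


@dataclass(frozen=True)
class EquilibriumConstants:
    """Equilibrium constants at one (T, S), NBS-scale convention.

    K0 in mol/kg/atm; K1, K2, KB, KW in mol/kg (with H as NBS activity);
    fH dimensionless; total_borate in mol/kg.
    """

    temperature: float
    salinity: float
    K0: float
    K1: float
    K2: float
    KB: float
    KW: float
    fH: float
    total_borate: float


@dataclass(frozen=True)
class CarbonateState:
    """A fully speciated carbonate-system state.

    pH on the NBS scale; pCO2 in uatm; DIC, TA and all species in umol/kg.
    The construction guarantees DIC = CO2* + HCO3 + CO3 and
    TA = HCO3 + 2 CO3 + B(OH)4 + OH - H(free).
    """

    temperature: float
    salinity: float
    pH: float
    pCO2: float
    dic: float
    ta: float
    co2_star: float
    hco3: float
    co3: float
    boh4: float
    oh: float
    h_free: float


@dataclass(frozen=True)
class RespirometerCO2Scenario:
    """Inputs for the closed-respirometer CO2-accumulation model.

    Defaults reproduce the published scenario: 15 degC, equilibration with
    a 395-uatm atmosphere, 140 umol/kg of respired CO2 (the DIC added by a
    fish depleting O2 from >20 kPa to ~6 kPa at RQ 0.85), over starting pH
    7.5-8.5 and salinity 20-40 PSU.
    """

    start_ph: tuple[float, ...] = (7.5, 7.75, 8.0, 8.25, 8.5)
    salinity: tuple[float, ...] = (20.0, 25.0, 30.0, 35.0, 40.0)
    temperature: float = 15.0
    atmospheric_pco2: float = 395.0
    delta_dic: float = 140.0
    respiratory_quotient: float = 0.85

    def __post_init__(self) -> None:
        if len(self.start_ph) == 0 or len(self.salinity) == 0:
            raise ValueError("start_ph and salinity grids must be non-empty")
        if self.delta_dic < 0:
            raise ValueError("delta_dic must be >= 0")
        if not 0 < self.respiratory_quotient <= 1.2:
            raise ValueError(
                f"respiratory quotient must lie in (0, 1.2], got {self.respiratory_quotient}"
            )


@dataclass
class RespirometerCO2Result:
    """Final pCO2 surface plus the audited initial/final states."""

    scenario: RespirometerCO2Scenario
    final_pco2: np.ndarray  # shape (n_ph, n_sal), uatm
    initial_states: list[list[CarbonateState]]
    final_states: list[list[CarbonateState]]

    def to_frame(self):
        """Tidy table: one row per (start_ph, salinity) cell."""
        import pandas as pd

        rows = []
        for i, ph in enumerate(self.scenario.start_ph):
            for j, s in enumerate(self.scenario.salinity):
                ini, fin = self.initial_states[i][j], self.final_states[i][j]
                rows.append(
                    {
                        "start_ph": ph,
                        "salinity": s,
                        "ta": ini.ta,
                        "dic_initial": ini.dic,
                        "dic_final": fin.dic,
                        "final_pco2_uatm": fin.pCO2,
                        "final_ph": fin.pH,
                    }
                )
        return pd.DataFrame(rows)


def constants(temperature: float, salinity: float) -> EquilibriumConstants:
    """Evaluate the pinned NBS-scale constant set at (T degC, S PSU).

    Valid over 0-40 degC and 19-43 PSU (the Mehrbach fit domain, padded by
    the published salinity grid).
    """
    if not 0.0 <= temperature <= 40.0:
        raise ValueError(
            f"temperature {temperature} degC outside the 0-40 validity range of the constant set"
        )
    if not 19.0 <= salinity <= 43.0:
        raise ValueError(
            f"salinity {salinity} PSU outside the 19-43 validity range of the constant set"
        )
    tk = temperature + 273.15
    s = salinity

    ln_k0 = (
        -60.2409
        + 93.4517 * (100.0 / tk)
        + 23.3585 * math.log(tk / 100.0)
        + s * (0.023517 - 0.023656 * (tk / 100.0) + 0.0047036 * (tk / 100.0) ** 2)
    )
    k0 = math.exp(ln_k0)

    pk1 = -13.7201 + 0.031334 * tk + 3235.76 / tk + 1.300e-5 * s * tk - 0.1032 * math.sqrt(s)
    pk2 = (
        5371.9645
        + 1.671221 * tk
        + 0.22913 * s
        + 18.3802 * math.log10(s)
        - 128375.28 / tk
        - 2194.3055 * math.log10(tk)
        - 8.0944e-4 * s * tk
        - 5617.11 * math.log10(s) / tk
        + 2.136 * s / tk
    )

    fh = 1.29 - 0.00204 * tk + 0.00046 * s**2 - 0.00000148 * s**2 * tk
    kb = 10.0 ** (-9.26 + 0.00886 * s + 0.01 * temperature)
    ln_kw = (
        148.9802
        - 13847.26 / tk
        - 23.6521 * math.log(tk)
        + (118.67 / tk - 5.977 + 1.0495 * math.log(tk)) * math.sqrt(s)
        - 0.01615 * s
    )
    kw = math.exp(ln_kw) * fh
    bt = 410.6e-6 * s / 35.0

    return EquilibriumConstants(
        temperature=temperature,
        salinity=salinity,
        K0=k0,
        K1=10.0**-pk1,
        K2=10.0**-pk2,
        KB=kb,
        KW=kw,
        fH=fh,
        total_borate=bt,
    )


def _assemble_state(ks: EquilibriumConstants, ph: float, co2_star_mol: float) -> CarbonateState:
    ah = 10.0**-ph
    hco3 = ks.K1 * co2_star_mol / ah
    co3 = ks.K2 * hco3 / ah
    boh4 = ks.total_borate * ks.KB / (ks.KB + ah)
    oh = ks.KW / ah
    h_free = ah / ks.fH
    dic = co2_star_mol + hco3 + co3
    ta = hco3 + 2.0 * co3 + boh4 + oh - h_free
    to_umol = 1e6
    return CarbonateState(
        temperature=ks.temperature,
        salinity=ks.salinity,
        pH=ph,
        pCO2=co2_star_mol / ks.K0 * 1e6,
        dic=dic * to_umol,
        ta=ta * to_umol,
        co2_star=co2_star_mol * to_umol,
        hco3=hco3 * to_umol,
        co3=co3 * to_umol,
        boh4=boh4 * to_umol,
        oh=oh * to_umol,
        h_free=h_free * to_umol,
    )


def state_from_ph_pco2(
    ph: float, pco2: float, temperature: float, salinity: float
) -> CarbonateState:
    """Speciate the carbonate system from (pH_NBS, pCO2 in uatm, T, S)."""
    if not 2.0 < ph < 12.0:
        raise ValueError(f"pH must lie in (2, 12), got {ph}")
    if pco2 <= 0:
        raise ValueError(f"pCO2 must be > 0, got {pco2}")
    ks = constants(temperature, salinity)
    co2_star = ks.K0 * pco2 * 1e-6  # mol/kg, via Henry's law
    return _assemble_state(ks, ph, co2_star)


def _ta_residual(ph: float, ta_mol: float, dic_mol: float, ks: EquilibriumConstants) -> float:
    ah = 10.0**-ph
    denom = 1.0 + ks.K1 / ah + ks.K1 * ks.K2 / ah**2
    co2_star = dic_mol / denom
    hco3 = ks.K1 * co2_star / ah
    co3 = ks.K2 * hco3 / ah
    ta_calc = (
        hco3
        + 2.0 * co3
        + ks.total_borate * ks.KB / (ks.KB + ah)
        + ks.KW / ah
        - ah / ks.fH
    )
    return ta_calc - ta_mol


def pco2_from_ta_dic(
    ta: float, dic: float, temperature: float, salinity: float
) -> CarbonateState:
    """Solve the carbonate system from (TA, DIC) in umol/kg.

    Brent root-finding on the alkalinity residual over pH in [2, 12];
    converged states satisfy |TA(pH) - TA| < 1e-4 umol/kg.
    """
    if ta <= 0 or dic <= 0:
        raise ValueError(f"TA and DIC must be positive, got TA={ta}, DIC={dic}")
    ks = constants(temperature, salinity)
    ta_mol, dic_mol = ta * 1e-6, dic * 1e-6
    lo, hi = 2.0, 12.0
    r_lo = _ta_residual(lo, ta_mol, dic_mol, ks)
    r_hi = _ta_residual(hi, ta_mol, dic_mol, ks)
    if r_lo * r_hi > 0:
        raise ValueError(
            "no pH root in [2, 12] for the given TA/DIC: residuals "
            f"{r_lo * 1e6:.3g} and {r_hi * 1e6:.3g} umol/kg at the bracket ends"
        )
    ph = brentq(
        _ta_residual, lo, hi, args=(ta_mol, dic_mol, ks), xtol=1e-13, rtol=8.9e-16
    )
    ah = 10.0**-ph
    co2_star = dic_mol / (1.0 + ks.K1 / ah + ks.K1 * ks.K2 / ah**2)
    state = _assemble_state(ks, ph, co2_star)
    if abs(state.ta - ta) > 1e-4:
        raise RuntimeError(
            f"alkalinity residual {abs(state.ta - ta):.2e} umol/kg exceeds tolerance"
        )
    return state


def respirometer_co2_model(
    scenario: RespirometerCO2Scenario | None = None,
) -> RespirometerCO2Result:
    """Final pCO2 reached in a closed respirometer, over a (pH, S) grid.

    For each grid cell the initial state is speciated from the starting pH
    at equilibrium with the atmospheric pCO2; the respired CO2 is then
    added to DIC while TA is held constant (dissolving CO2 does not change
    alkalinity) and the final state is solved from (TA, DIC + delta).
    TA conservation is asserted on every cell.
    """
    if scenario is None:
        scenario = RespirometerCO2Scenario()
    n_ph, n_s = len(scenario.start_ph), len(scenario.salinity)
    final = np.empty((n_ph, n_s))
    initial_states: list[list[CarbonateState]] = []
    final_states: list[list[CarbonateState]] = []
    for i, ph in enumerate(scenario.start_ph):
        row_i, row_f = [], []
        for j, s in enumerate(scenario.salinity):
            ini = state_from_ph_pco2(ph, scenario.atmospheric_pco2, scenario.temperature, s)
            fin = pco2_from_ta_dic(
                ini.ta, ini.dic + scenario.delta_dic, scenario.temperature, s
            )
            if abs(fin.ta - ini.ta) > 1e-4:
                raise RuntimeError("TA not conserved through the respirometer model")
            final[i, j] = fin.pCO2
            row_i.append(ini)
            row_f.append(fin)
        initial_states.append(row_i)
        final_states.append(row_f)
    return RespirometerCO2Result(
        scenario=scenario,
        final_pco2=final,
        initial_states=initial_states,
        final_states=final_states,
    )


def delta_dic_from_o2(
    po2_start: float,
    po2_end: float,
    respiratory_quotient: float,
    conditions: WaterConditions,
) -> float:
    """DIC added (umol/kg) by respiration depleting O2 between two PO2.

    delta_DIC = RQ * (C(po2_start) - C(po2_end)) with the dissolved-O2
    concentrations from the solubility model, expressed per kilogram.
    """
    if not po2_start > po2_end >= 0:
        raise ValueError(
            f"require po2_start > po2_end >= 0, got {po2_start} and {po2_end}"
        )
    c_sat_mg_l, _ = o2_solubility(conditions)
    rho = seawater_density(conditions.temperature, conditions.salinity)
    # umol/kg per kPa of PO2
    beta_umol_kg = c_sat_mg_l / (31.998e-3 * rho) / po2_air_saturation(conditions)
    return respiratory_quotient * beta_umol_kg * (po2_start - po2_end)
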