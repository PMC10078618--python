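"""Annual wetland carbon-budget accounting from treatment component data.

Given per-treatment annual means of productivity (ANPP, BNPP), litter
decomposition (D_AG, D_BG, losses negative), net ecosystem CO2 exchange
(NEE, release positive), methane flux (F_CH4), observed peat-depth change
(ΔPD) and soil physical properties, this module chains

    ΔST  = (1-α)·ΔPD·ρ_b·10⁴ - (D_AG + D_BG)        soil-material change
    ΔSC  = ΔST · f_C                                 soil-carbon change
    NECB = ANPP + BNPP + D_AG + D_BG + ΔSC - F_CH4   pool-based C balance
    F_R  = -NEE - F_CH4 - NECB                       residual flux
    F_AQ = F_R - ΔSC                                 net aquatic flux

with a CO2-equivalent emission magnitude |ΔSC|·3.67/100 in Mg CO2 ha⁻¹ yr⁻¹.
Positive NECB is net accumulation; positive F_R/F_AQ are net export.  The
decomposition terms enter the soil-material equation in carbon units without
an f_C conversion — that is the convention of the source budgets, verified
against every published treatment column, and is kept as-is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import InvalidInputError

__all__ = [
    "TreatmentBudgetInputs",
    "BudgetResult",
    "degree_of_compaction",
    "delta_soil_mass",
    "delta_soil_carbon",
    "necb_from_pools",
    "residual_flux",
    "aquatic_flux",
    "co2_equivalent",
    "budget_table",
    "round_half_away",
]

#: cm · g cm^-3 -> g m^-2
_CM_G_CM3_TO_G_M2 = 1.0e4
#: gC -> g CO2 mass conversion (44/12)
_C_TO_CO2 = 3.67
#: g m^-2 -> Mg ha^-1
_G_M2_TO_MG_HA = 0.01


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of the printed budgets)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class TreatmentBudgetInputs:
    """Annual C-budget components for one treatment.

    Units: C fluxes in gC m⁻² yr⁻¹ (losses negative for d_ag/d_bg; release
    positive for nee and f_ch4), delta_pd_cm in cm yr⁻¹ (gain positive),
    bulk densities in g cm⁻³, f_c and alpha dimensionless.
    """

    treatment_id: str
    anpp: float
    bnpp: float
    d_ag: float
    d_bg: float
    nee: float
    f_ch4: float
    delta_pd_cm: float
    rho_b_field: float
    rho_b_exp: float
    f_c: float
    alpha: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_c <= 1.0:
            raise InvalidInputError(f"{self.treatment_id}: f_c must be in [0, 1]")
        if not 0.0 <= self.alpha < 1.0:
            raise InvalidInputError(f"{self.treatment_id}: alpha must be in [0, 1)")
        if self.rho_b_field <= 0 or self.rho_b_exp <= 0:
            raise InvalidInputError(f"{self.treatment_id}: bulk densities must be positive")
        if self.anpp < 0 or self.bnpp < 0:
            raise InvalidInputError(f"{self.treatment_id}: productivity must be >= 0")


@dataclass(frozen=True)
class BudgetResult:
    """Derived annual budget terms for one treatment (full precision)."""

    treatment_id: str
    delta_st: float  # g m-2 yr-1
    delta_sc: float  # gC m-2 yr-1
    necb: float      # gC m-2 yr-1
    f_r: float       # gC m-2 yr-1
    f_aq: float      # gC m-2 yr-1
    co2_eq: float    # Mg CO2 ha-1 yr-1, magnitude


def degree_of_compaction(rho_b_exp: float, rho_b_field: float) -> float:
    """Fractional bulk-density change of the experiment soil vs the field.

    Positive values indicate compaction; negative values indicate swelling.
    """
    if rho_b_exp <= 0 or rho_b_field <= 0:
        raise InvalidInputError("bulk densities must be positive")
    return (rho_b_exp - rho_b_field) / rho_b_field


def delta_soil_mass(
    delta_pd: float,
    alpha: float,
    rho_b_field: float,
    d_ag: float,
    d_bg: float,
) -> float:
    """Net annual soil-material change ΔST in g m⁻² yr⁻¹.

    The observed peat-depth change is first reduced by the compaction
    fraction (only (1-α) of the depth change is material change), converted
    to mass with the pre-experiment field bulk density, and the decomposition
    losses are subtracted out to avoid counting them twice.
    """
    if alpha >= 1.0:
        raise InvalidInputError("alpha must be < 1 (1 would be total compaction)")
    if d_ag > 0 or d_bg > 0:
        raise InvalidInputError("decomposition fluxes carry the loss (negative) sign")
    material = (1.0 - alpha) * delta_pd * rho_b_field * _CM_G_CM3_TO_G_M2
    return material - (d_ag + d_bg)


def delta_soil_carbon(delta_st: float, f_c: float) -> float:
    """Soil-carbon change ΔSC = ΔST·f_C in gC m⁻² yr⁻¹ (sign preserved)."""
    if not 0.0 <= f_c <= 1.0:
        raise InvalidInputError("f_c must be in [0, 1]")
    return delta_st * f_c


def necb_from_pools(inputs: TreatmentBudgetInputs, delta_sc: float) -> float:
    """Net ecosystem C balance from the C-pool mass balance.

    NECB = ANPP + BNPP + D_AG + D_BG + ΔSC - F_CH4, with the decomposition
    terms carrying their loss (negative) sign.  Positive = net accumulation.
    """
    return (
        inputs.anpp + inputs.bnpp + inputs.d_ag + inputs.d_bg + delta_sc - inputs.f_ch4
    )


def residual_flux(nee: float, f_ch4: float, necb: float) -> float:
    """Residual flux F_R = -NEE - F_CH4 - NECB (positive = net export)."""
    return -nee - f_ch4 - necb


def aquatic_flux(f_r: float, delta_sc: float) -> float:
    """Net aquatic flux F_AQ = F_R - ΔSC, assuming negligible particulate flux."""
    return f_r - delta_sc


def co2_equivalent(delta_sc: float) -> float:
    """CO2-equivalent emission magnitude of a soil-C change, Mg CO2 ha⁻¹ yr⁻¹."""
    return abs(delta_sc) * _C_TO_CO2 * _G_M2_TO_MG_HA


def compute_budget(inputs: TreatmentBudgetInputs) -> BudgetResult:
    """Chain the full budget for one treatment record."""
    delta_st = delta_soil_mass(
        inputs.delta_pd_cm, inputs.alpha, inputs.rho_b_field, inputs.d_ag, inputs.d_bg
    )
    delta_sc = delta_soil_carbon(delta_st, inputs.f_c)
    necb = necb_from_pools(inputs, delta_sc)
    f_r = residual_flux(inputs.nee, inputs.f_ch4, necb)
    f_aq = aquatic_flux(f_r, delta_sc)
    return BudgetResult(
        treatment_id=inputs.treatment_id,
        delta_st=delta_st,
        delta_sc=delta_sc,
        necb=necb,
        f_r=f_r,
        f_aq=f_aq,
        co2_eq=co2_equivalent(delta_sc),
    )


def budget_table(records: Iterable[TreatmentBudgetInputs]) -> list[BudgetResult]:
    """Compute budgets for a batch of treatment records, preserving order."""
    records = list(records)
    if not records:
        raise InvalidInputError("budget_table needs at least one treatment record")
    results = []
    for rec in records:
        try:
            results.append(compute_budget(rec))
        except InvalidInputError as exc:
            raise InvalidInputError(f"treatment {rec.treatment_id!r}: {exc}") from exc
    return results


def budget_frame(results: Sequence[BudgetResult]) -> pd.DataFrame:
    """Budget results as a DataFrame in input row order."""
    return pd.DataFrame(
        {
            "treatment_id": [r.treatment_id for r in results],
            "delta_st": [r.delta_st for r in results],
            "delta_sc": [r.delta_sc for r in results],
            "necb": [r.necb for r in results],
            "f_r": [r.f_r for r in results],
            "f_aq": [r.f_aq for r in results],
            "co2_eq": [r.co2_eq for r in results],
        }
    )
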