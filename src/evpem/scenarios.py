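"""Multi-decade scenario engine and NPP-threshold optimization.

Builds 30-year forcing trajectories (linear NPP and salinity ramps, a
seasonal water-level template with a sea-level-rise trend), runs the daily
simulator, summarizes hydroperiod and elevation trends, classifies the
trajectory (accumulating / steady / collapsing) and searches, by bisection,
for the annual net primary productivity that holds the peat elevation at a
target change rate for a given salinity.

Scenario simulations clamp the salinity-driven soil-change term to losses
(``delta_st_losses_only``): the exposed-regime response fits are supported
by data at 10-20 ppt only, and extrapolating them below that range predicts
soil accumulation with zero productivity; in the forward model accumulation
is carried by the litter pathway alone, so the salinity term contributes
only the oxidation/export loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core import DAYS_PER_YEAR, ForcingSeries, ModelConfig, SimulationResult, annualize, simulate
from .exceptions import InvalidInputError
from .response import ResponseCoefficients, anpp_of_salinity, bnpp_of_salinity

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "ThresholdResult",
    "seasonal_water_level",
    "linear_trajectory",
    "run_scenario",
    "classify_trajectory",
    "npp_threshold",
]

_MONTH_LENGTHS = (31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31)

#: classification tolerance on the elevation-change rate, mm yr^-1
RATE_TOLERANCE_MM_YR = 0.5


@dataclass(frozen=True)
class ScenarioSpec:
    """Description of a multi-year forcing scenario.

    The default seasonal template is 8 months of submergence, 3 months of
    moderate exposure and 1 month of high exposure, realized with
    representative water depths of +5 / -3 / -10 cm relative to ``pe0``
    (only the exposure class, not the depth magnitude, enters the rate
    equations).  The water level rises by ``slr`` cm yr⁻¹ throughout.
    """

    years: int = 30
    slr: float = 0.3  # cm yr-1
    season_months: tuple[int, int, int] = (8, 3, 1)  # submerged / moderate / high
    season_depths: tuple[float, float, float] = (5.0, -3.0, -10.0)  # cm rel. to pe0
    npp_start: float = 130.0  # gC m-2 yr-1
    npp_end: float = 440.0
    sal_start: float = 1.0  # ppt
    sal_end: float = 20.0
    ag_bg_split: str = "productivity_curves"  # or "fixed"
    ag_fraction: float = 0.85  # used only with ag_bg_split="fixed"
    tr_ag: float = 1.5  # yr-1
    tr_bg: float = 0.5
    rho_b: float = 0.13  # g cm-3
    alpha: float = 0.1
    f_c: float = 0.43
    f_ch4: float = 0.0  # gC m-2 yr-1
    pe0: float = 0.0  # cm NAVD88
    ls_ag0: float = 300.0  # g m-2
    ls_bg0: float = 50.0

    def __post_init__(self) -> None:
        if sum(self.season_months) != 12:
            raise InvalidInputError("season months must sum to 12")
        if self.years < 1:
            raise InvalidInputError("years must be >= 1")

    def model_config(self) -> ModelConfig:
        return ModelConfig(
            h0=1.5,
            rho_b=self.rho_b,
            alpha=self.alpha,
            f_c=self.f_c,
            tr_ag=self.tr_ag,
            tr_bg=self.tr_bg,
            ls_ag0=self.ls_ag0,
            ls_bg0=self.ls_bg0,
            pe0=self.pe0,
            eb=self.pe0,
            delta_st_losses_only=True,
        )


@dataclass
class ScenarioResult:
    """Summary of one scenario run."""

    annual_pe_cm: np.ndarray  # year-end elevation, cm NAVD88
    pe_rate_mm_yr: float      # OLS slope of year-end PE vs year
    wet_days: np.ndarray      # per-year hydroperiod, days
    ponding_rate_mm_yr: float  # slr - pe rate
    label: str
    year_full_submergence: int | None
    simulation: SimulationResult = field(repr=False, default=None)


def seasonal_water_level(spec: ScenarioSpec, pe_ref: float) -> np.ndarray:
    """One year of daily water levels realizing the seasonal template.

    Calendar months are assigned in order: the first ``season_months[0]``
    months at the submerged depth, then the moderate-exposure months, then
    the high-exposure month(s), each as a constant level relative to
    ``pe_ref``.  The sea-level trend is added by the caller.
    """
    if sum(spec.season_months) != 12:
        raise InvalidInputError("season months must sum to 12")
    depths = np.concatenate(
        [
            np.full(n_months, depth)
            for n_months, depth in zip(spec.season_months, spec.season_depths)
        ]
    )
    wl = np.concatenate(
        [np.full(days, pe_ref + depths[m]) for m, days in enumerate(_MONTH_LENGTHS)]
    )
    return wl


def linear_trajectory(start: float, end: float, n_days: int) -> np.ndarray:
    """Daily linear ramp inclusive of both endpoints."""
    if n_days < 2:
        raise InvalidInputError("a trajectory needs at least 2 days")
    return np.linspace(start, end, n_days)


def _split_npp(
    npp: np.ndarray, sal: np.ndarray, spec: ScenarioSpec, coeffs: ResponseCoefficients
) -> tuple[np.ndarray, np.ndarray]:
    """Partition total NPP into ANPP/BNPP shares (annual units)."""
    if spec.ag_bg_split == "fixed":
        frac = np.full_like(npp, spec.ag_fraction)
    elif spec.ag_bg_split == "productivity_curves":
        ag = np.array([anpp_of_salinity(s, coeffs) for s in sal])
        bg = np.array([bnpp_of_salinity(s, coeffs) for s in sal])
        total = ag + bg
        frac = np.where(total > 0, ag / np.where(total > 0, total, 1.0), 1.0)
    else:
        raise InvalidInputError(f"unknown ag_bg_split {spec.ag_bg_split!r}")
    return npp * frac, npp * (1.0 - frac)


def build_forcing(spec: ScenarioSpec, coeffs: ResponseCoefficients) -> ForcingSeries:
    """Assemble the daily forcing for a scenario."""
    n_days = spec.years * DAYS_PER_YEAR
    sal = linear_trajectory(spec.sal_start, spec.sal_end, n_days)
    npp = linear_trajectory(spec.npp_start, spec.npp_end, n_days)
    anpp, bnpp = _split_npp(npp, sal, spec, coeffs)
    template = seasonal_water_level(spec, spec.pe0)
    t = np.arange(n_days)
    wl = template[t % DAYS_PER_YEAR] + spec.slr * t / DAYS_PER_YEAR
    return ForcingSeries.from_annual(
        anpp=anpp,
        bnpp=bnpp,
        f_ch4=np.full(n_days, spec.f_ch4),
        sal=sal,
        wl=wl,
    )


def _pe_rate_mm_yr(annual_pe: np.ndarray, pe0: float) -> float:
    """OLS slope of year-end elevation vs year, in mm yr⁻¹."""
    pe = np.concatenate([[pe0], annual_pe])
    years = np.arange(pe.size, dtype=float)
    slope_cm = float(np.polyfit(years, pe, 1)[0])
    return slope_cm * 10.0


def classify_trajectory(pe_rate_mm_yr: float, slr_mm_yr: float) -> str:
    """Label a trajectory from its elevation-change rate vs sea-level rise.

    ``accumulating`` keeps pace with SLR (rate >= slr - tolerance),
    ``collapsing`` loses elevation (rate < 0), everything else is ``steady``.
    The tolerance is 0.5 mm yr⁻¹.
    """
    if pe_rate_mm_yr >= slr_mm_yr - RATE_TOLERANCE_MM_YR:
        return "accumulating"
    if pe_rate_mm_yr < 0.0:
        return "collapsing"
    return "steady"


def run_scenario(
    spec: ScenarioSpec, coeffs: ResponseCoefficients | None = None
) -> ScenarioResult:
    """Run a scenario end-to-end and summarize it."""
    coeffs = coeffs or ResponseCoefficients.default()
    forcing = build_forcing(spec, coeffs)
    sim = simulate(spec.model_config(), forcing, coeffs)
    annual = annualize(sim)
    annual_pe = annual["pe_end_cm"].to_numpy()
    wet_days = annual["wet_days"].to_numpy()
    rate = _pe_rate_mm_yr(annual_pe, spec.pe0)
    slr_mm = spec.slr * 10.0
    full = np.flatnonzero(wet_days >= DAYS_PER_YEAR)
    return ScenarioResult(
        annual_pe_cm=annual_pe,
        pe_rate_mm_yr=rate,
        wet_days=wet_days,
        ponding_rate_mm_yr=slr_mm - rate,
        label=classify_trajectory(rate, slr_mm),
        year_full_submergence=int(full[0]) + 1 if full.size else None,
        simulation=sim,
    )


@dataclass
class ThresholdResult:
    """Outcome of an NPP-threshold search."""

    npp: float | None          # gC m-2 yr-1, None if unattainable
    achieved_rate_mm_yr: float
    target_rate_mm_yr: float
    sal: float
    attainable: bool
    iterations: int


def _threshold_rate(
    npp: float,
    sal: float,
    spec: ScenarioSpec,
    coeffs: ResponseCoefficients,
    horizon_years: int,
) -> float:
    """Simulated PE change rate (mm yr⁻¹) at constant NPP and salinity."""
    one_year = replace(
        spec,
        years=horizon_years,
        npp_start=npp,
        npp_end=npp,
        sal_start=sal,
        sal_end=sal,
    )
    forcing = build_forcing(one_year, coeffs)
    sim = simulate(one_year.model_config(), forcing, coeffs)
    pe_end = float(sim.daily["pe"].iloc[-1])
    return (pe_end - one_year.pe0) * 10.0 / horizon_years


def npp_threshold(
    sal: float,
    target_rate_mm_yr: float,
    spec: ScenarioSpec | None = None,
    coeffs: ResponseCoefficients | None = None,
    horizon_years: int = 1,
    bracket: tuple[float, float] = (0.0, 2000.0),
    rate_tol_mm_yr: float = 0.05,
    max_iter: int = 60,
) -> ThresholdResult:
    """Minimal annual NPP that sustains a target elevation-change rate.

    Bisects total annual NPP (partitioned per the scenario's AG:BG rule)
    until the simulated elevation-change rate at the given salinity matches
    ``target_rate_mm_yr`` within ``rate_tol_mm_yr``.  The rate is a monotone
    non-decreasing, piecewise-linear function of NPP (the litter-transfer
    clamp creates flat segments), so bisection is deterministic.  If even the
    upper bracket cannot reach the target the result is flagged unattainable.
    """
    spec = spec or ScenarioSpec()
    coeffs = coeffs or ResponseCoefficients.default()
    lo, hi = bracket
    rate = lambda npp: _threshold_rate(npp, sal, spec, coeffs, horizon_years)
    f_lo = rate(lo)
    if f_lo >= target_rate_mm_yr:
        return ThresholdResult(lo, f_lo, target_rate_mm_yr, sal, True, 0)
    f_hi = rate(hi)
    if f_hi < target_rate_mm_yr - rate_tol_mm_yr:
        logger.warning(
            "NPP threshold unattainable at sal=%.3g: rate(%.0f)=%.3f mm/yr < target %.3f",
            sal, hi, f_hi, target_rate_mm_yr,
        )
        return ThresholdResult(None, f_hi, target_rate_mm_yr, sal, False, 1)
    iterations = 0
    mid = hi
    f_mid = f_hi
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        f_mid = rate(mid)
        if abs(f_mid - target_rate_mm_yr) <= rate_tol_mm_yr or (hi - lo) < 1e-6 * bracket[1]:
            break
        if f_mid < target_rate_mm_yr:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(mid, f_mid, target_rate_mm_yr, sal, True, iterations)
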