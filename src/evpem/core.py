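"""Daily stock-and-flow simulator for peat mass, elevation and water level.

The peat soil column is modelled as a single mass stock MS (g m⁻²) fed by
the above- and belowground litter pathways and drained by methane loss and a
salinity-driven soil-material change term:

    MS_t = MS_{t-1} + C_AG + C_BG + ΔST - F_CH4

Litter production LP = NPP·TR flows into an above-/belowground litter stock
LS; decomposition D = LS·k leaves it; the surplus C = max(LP - D, 0) is
transferred to the soil.  When decomposition exceeds production the litter
stock is drawn down and nothing reaches the soil.  The simulated stock is
converted to an equivalent peat depth PD_e = MS/ρ_b, the depth increment is
amplified by compaction (ΔPD_a = ΔPD_e/(1-α)) and accumulated into the peat
elevation PE (cm NAVD 88).  Water depth WD = WL - PE selects the exposure
regime each sub-step, and the water level can advance with a sea-level-rise
increment.  Integration is explicit Euler with 1/dt uniform sub-steps per
day (default dt = 0.125, i.e. 8 sub-steps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InvalidInputError
from .response import (
    ExposureRegime,
    ResponseCoefficients,
    classify_regime,
    delta_st_rate,
    k_rate,
    mbe,
    nse,
)

__all__ = [
    "ModelConfig",
    "ForcingSeries",
    "ModelState",
    "DailyOutput",
    "SimulationResult",
    "init_state",
    "step",
    "simulate",
    "annualize",
    "calibrate_compare",
    "run_treatment",
]

DAYS_PER_YEAR = 365
#: cm · g cm^-3 -> g m^-2 (area unit conversion)
_CM_G_CM3_TO_G_M2 = 1.0e4


@dataclass(frozen=True)
class ModelConfig:
    """Static simulator configuration.

    Parameters
    ----------
    h0 : float
        Initial peat depth over bedrock, m.
    rho_b : float
        Soil bulk density, g cm⁻³.
    alpha : float or sequence of float
        Degree of compaction (0 ≤ α < 1); a scalar or a per-day series.
    f_c : float
        Soil C mass fraction (used for the daily soil-C and NECB outputs).
    tr_ag, tr_bg : float
        Turnover multipliers (yr⁻¹) applied to the annual productivity before
        downscaling, so daily litter production is NPP_annual·TR/365.
    ls_ag0, ls_bg0 : float
        Initial above-/belowground litter stocks, g m⁻².
    pe0, eb : float
        Initial peat elevation and the elevation benchmark, cm NAVD 88.
    dt : float
        Euler sub-step fraction of a day; 1/dt must be an integer.
    delta_st_losses_only : bool
        If set, the salinity-driven ΔST term is clamped to losses (≤ 0).
        Off by default (treatment hindcasts); forward scenarios switch it on
        so that soil accumulation is carried only by the litter pathway.
    """

    h0: float = 1.5
    rho_b: float = 0.13
    alpha: float | Sequence[float] = 0.1
    f_c: float = 0.43
    tr_ag: float = 1.5
    tr_bg: float = 0.5
    ls_ag0: float = 300.0
    ls_bg0: float = 50.0
    pe0: float = 0.0
    eb: float = 0.0
    dt: float = 0.125
    sal_floor: float = 0.1
    delta_st_losses_only: bool = False

    def __post_init__(self) -> None:
        if self.h0 <= 0:
            raise ConfigurationError("h0 must be positive")
        if self.rho_b <= 0:
            raise ConfigurationError("rho_b must be positive")
        if not 0 < self.dt <= 1 or abs(round(1 / self.dt) - 1 / self.dt) > 1e-9:
            raise ConfigurationError("dt must be in (0, 1] with integer 1/dt")
        alphas = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if np.any(alphas < 0) or np.any(alphas >= 1):
            raise ConfigurationError("alpha must satisfy 0 <= alpha < 1 at every day")
        if self.ls_ag0 < 0 or self.ls_bg0 < 0:
            raise ConfigurationError("initial litter stocks must be >= 0")

    def alpha_at(self, day: int) -> float:
        """Degree of compaction for a given day (scalar configs are constant)."""
        if np.isscalar(self.alpha):
            return float(self.alpha)
        seq = np.asarray(self.alpha, dtype=float)
        if day >= seq.size:
            raise InvalidInputError(f"alpha series too short for day {day}")
        return float(seq[day])

    @property
    def substeps(self) -> int:
        return round(1 / self.dt)


@dataclass
class ForcingSeries:
    """Daily driver vectors.

    ``anpp``/``bnpp``/``f_ch4`` are gC m⁻² day⁻¹ (use ``from_annual`` to
    divide annual inputs by 365), ``sal`` is ppt, and either ``wl`` (absolute
    water level, cm NAVD 88, held fixed within a day) or ``slr`` (daily
    water-level increments, cm day⁻¹, integrated from ``wl0``) must be given.
    """

    anpp: np.ndarray
    bnpp: np.ndarray
    f_ch4: np.ndarray
    sal: np.ndarray
    wl: np.ndarray | None = None
    slr: np.ndarray | None = None
    wl0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("anpp", "bnpp", "f_ch4", "sal", "wl", "slr"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, np.asarray(value, dtype=float))
        n = self.anpp.size
        if n < 1:
            raise InvalidInputError("forcing must span at least one day")
        if (self.wl is None) == (self.slr is None):
            raise InvalidInputError("provide exactly one of wl or slr")
        for name in ("anpp", "bnpp", "f_ch4", "sal", "wl", "slr"):
            vec = getattr(self, name)
            if vec is None:
                continue
            if vec.ndim != 1 or vec.size != n:
                raise InvalidInputError(f"forcing column {name!r} must have length {n}")
            bad = np.flatnonzero(~np.isfinite(vec))
            if bad.size:
                raise InvalidInputError(f"NaN/inf in forcing column {name!r} at day {bad[0]}")
        if np.any(self.sal < 0):
            raise InvalidInputError("salinity must be >= 0")

    def __len__(self) -> int:
        return int(self.anpp.size)

    @classmethod
    def from_annual(
        cls,
        anpp,
        bnpp,
        f_ch4,
        sal,
        wl=None,
        slr=None,
        wl0: float = 0.0,
    ) -> "ForcingSeries":
        """Build a series from annual-unit fluxes (divided by 365 per day)."""
        scale = lambda v: np.asarray(v, dtype=float) / DAYS_PER_YEAR
        return cls(
            anpp=scale(anpp), bnpp=scale(bnpp), f_ch4=scale(f_ch4),
            sal=np.asarray(sal, dtype=float), wl=wl, slr=slr, wl0=wl0,
        )


@dataclass
class ModelState:
    """Instantaneous simulator state."""

    day: int
    ms: float      # peat stock, g m-2
    ls_ag: float   # aboveground litter stock, g m-2
    ls_bg: float   # belowground litter stock, g m-2
    pde: float     # equivalent peat depth, cm
    pe: float      # peat elevation, cm NAVD 88
    wl: float      # water level, cm NAVD 88
    exhausted: bool = False  # peat stock hit bedrock (MS floored at 0)


@dataclass
class DailyOutput:
    """Per-day diagnostic flows (sub-step flows accumulated over the day)."""

    day: int
    regime: ExposureRegime
    wd: float
    lp_ag: float
    lp_bg: float
    d_ag: float
    d_bg: float
    c_ag: float
    c_bg: float
    delta_st: float
    delta_sc: float
    necb: float
    pe: float


@dataclass
class SimulationResult:
    daily: pd.DataFrame
    final_state: ModelState
    config: ModelConfig = field(repr=False, default=None)

    @property
    def ms_initial(self) -> float:
        return float(self._ms_initial)


def init_state(config: ModelConfig) -> ModelState:
    """Initial state: peat stock from the initial depth and bulk density."""
    ms = config.h0 * 100.0 * config.rho_b * _CM_G_CM3_TO_G_M2
    return ModelState(
        day=0,
        ms=ms,
        ls_ag=config.ls_ag0,
        ls_bg=config.ls_bg0,
        pde=ms / (config.rho_b * _CM_G_CM3_TO_G_M2),
        pe=config.pe0,
        wl=0.0,
    )


def _one_day(
    state: ModelState,
    anpp: float,
    bnpp: float,
    f_ch4: float,
    sal: float,
    wl: float | None,
    slr: float | None,
    coeffs: ResponseCoefficients,
    config: ModelConfig,
) -> DailyOutput:
    """Advance the state by one day in place and return the day's flows."""
    dt = config.dt
    alpha = config.alpha_at(state.day)
    rho_area = config.rho_b * _CM_G_CM3_TO_G_M2
    if wl is not None:
        state.wl = wl
    lp_ag = anpp * config.tr_ag
    lp_bg = bnpp * config.tr_bg
    wd0 = state.wl - state.pe
    regime0 = classify_regime(wd0)

    sum_d_ag = sum_d_bg = sum_c_ag = sum_c_bg = sum_dst = sum_fch4 = 0.0
    for _ in range(config.substeps):
        regime = classify_regime(state.wl - state.pe)
        d_ag = state.ls_ag * k_rate(sal, regime, "aboveground", coeffs)
        d_bg = state.ls_bg * k_rate(sal, regime, "belowground", coeffs)
        # Litter stock receives LP and is drained by decomposition and the
        # soil transfer: with LP > D the stock is unchanged and C = LP - D;
        # otherwise C = 0 and the stock declines by the deficit (never below 0).
        if lp_ag > d_ag:
            c_ag = lp_ag - d_ag
        else:
            c_ag = 0.0
            available = state.ls_ag / dt + lp_ag
            d_ag = min(d_ag, available)
            state.ls_ag = max(state.ls_ag - (d_ag - lp_ag) * dt, 0.0)
        if lp_bg > d_bg:
            c_bg = lp_bg - d_bg
        else:
            c_bg = 0.0
            available = state.ls_bg / dt + lp_bg
            d_bg = min(d_bg, available)
            state.ls_bg = max(state.ls_bg - (d_bg - lp_bg) * dt, 0.0)

        dst = delta_st_rate(sal, regime, coeffs)
        if config.delta_st_losses_only and dst > 0.0:
            dst = 0.0
        net = c_ag + c_bg + dst - f_ch4
        dms = net * dt
        if state.ms + dms < 0.0:
            # Bedrock: peat is exhausted; absorb the shortfall into the soil
            # term so the recorded flows still integrate to the stock change.
            dst += (-(state.ms + dms)) / dt
            dms = -state.ms
            state.exhausted = True
        prev_pde = state.pde
        state.ms += dms
        state.pde = state.ms / rho_area
        dpde = state.pde - prev_pde
        state.pe += dpde / (1.0 - alpha)
        if slr is not None:
            state.wl += slr * dt

        sum_d_ag += d_ag * dt
        sum_d_bg += d_bg * dt
        sum_c_ag += c_ag * dt
        sum_c_bg += c_bg * dt
        sum_dst += dst * dt
        sum_fch4 += f_ch4 * dt

    state.day += 1
    delta_sc = sum_dst * config.f_c
    necb = (
        anpp + bnpp - sum_d_ag - sum_d_bg + delta_sc - sum_fch4
    )
    return DailyOutput(
        day=state.day - 1,
        regime=regime0,
        wd=wd0,
        lp_ag=lp_ag,
        lp_bg=lp_bg,
        d_ag=sum_d_ag,
        d_bg=sum_d_bg,
        c_ag=sum_c_ag,
        c_bg=sum_c_bg,
        delta_st=sum_dst,
        delta_sc=delta_sc,
        necb=necb,
        pe=state.pe,
    )


def step(
    state: ModelState,
    day_forcing: dict,
    coeffs: ResponseCoefficients,
    config: ModelConfig,
) -> tuple[ModelState, DailyOutput]:
    """Advance one day from a one-day forcing slice.

    ``day_forcing`` maps ``anpp``/``bnpp``/``f_ch4``/``sal`` (per-day units)
    plus either ``wl`` or ``slr``.  Returns the new state (the input state is
    not mutated) and the day's flow diagnostics.
    """
    for key in ("anpp", "bnpp", "f_ch4", "sal"):
        if key not in day_forcing:
            raise InvalidInputError(f"day forcing missing {key!r}")
        if not math.isfinite(day_forcing[key]):
            raise InvalidInputError(f"non-finite forcing {key!r} at day {state.day}")
    new = replace(state)
    out = _one_day(
        new,
        anpp=day_forcing["anpp"],
        bnpp=day_forcing["bnpp"],
        f_ch4=day_forcing["f_ch4"],
        sal=day_forcing["sal"],
        wl=day_forcing.get("wl"),
        slr=day_forcing.get("slr"),
        coeffs=coeffs,
        config=config,
    )
    return new, out


def simulate(
    config: ModelConfig,
    forcing: ForcingSeries,
    coeffs: ResponseCoefficients | None = None,
) -> SimulationResult:
    """Run the daily simulator over a full forcing series.

    The recorded daily flows integrate exactly to the peat-stock change:
    ms_final - ms_initial == Σ(c_ag + c_bg + delta_st - f_ch4) over all days.
    """
    coeffs = coeffs or ResponseCoefficients.default()
    state = init_state(config)
    ms_initial = state.ms
    state.wl = forcing.wl[0] if forcing.wl is not None else forcing.wl0
    rows = []
    n = len(forcing)
    for day in range(n):
        out = _one_day(
            state,
            anpp=float(forcing.anpp[day]),
            bnpp=float(forcing.bnpp[day]),
            f_ch4=float(forcing.f_ch4[day]),
            sal=float(forcing.sal[day]),
            wl=float(forcing.wl[day]) if forcing.wl is not None else None,
            slr=float(forcing.slr[day]) if forcing.slr is not None else None,
            coeffs=coeffs,
            config=config,
        )
        rows.append(out)
    daily = pd.DataFrame(
        {
            "day": [r.day for r in rows],
            "regime": [r.regime.value for r in rows],
            "wd": [r.wd for r in rows],
            "lp_ag": [r.lp_ag for r in rows],
            "lp_bg": [r.lp_bg for r in rows],
            "d_ag": [r.d_ag for r in rows],
            "d_bg": [r.d_bg for r in rows],
            "c_ag": [r.c_ag for r in rows],
            "c_bg": [r.c_bg for r in rows],
            "delta_st": [r.delta_st for r in rows],
            "delta_sc": [r.delta_sc for r in rows],
            "necb": [r.necb for r in rows],
            "pe": [r.pe for r in rows],
        }
    )
    result = SimulationResult(daily=daily, final_state=state, config=config)
    result._ms_initial = ms_initial
    return result


def annualize(result: SimulationResult) -> pd.DataFrame:
    """Annual summaries: PE change (cm yr⁻¹), NECB sum, wet-day count.

    Years are consecutive 365-day blocks; trailing partial years are dropped.
    """
    daily = result.daily
    n_years = len(daily) // DAYS_PER_YEAR
    if n_years < 1:
        raise InvalidInputError("annualize needs at least 365 simulated days")
    pe0 = result.config.pe0 if result.config is not None else daily["pe"].iloc[0]
    rows = []
    prev_pe = pe0
    for year in range(n_years):
        block = daily.iloc[year * DAYS_PER_YEAR : (year + 1) * DAYS_PER_YEAR]
        end_pe = float(block["pe"].iloc[-1])
        rows.append(
            {
                "year": year + 1,
                "pe_change_cm": end_pe - prev_pe,
                "pe_end_cm": end_pe,
                "necb_gc_m2": float(block["necb"].sum()),
                "wet_days": int((block["wd"] >= 0).sum()),
            }
        )
        prev_pe = end_pe
    return pd.DataFrame(rows)


def calibrate_compare(simulated: Sequence[float], observed: Sequence[float]) -> dict:
    """NSE and MBE of simulated vs observed per-treatment annual values."""
    sim = np.asarray(simulated, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if sim.shape != obs.shape:
        raise InvalidInputError("simulated and observed must have equal length")
    return {"nse": nse(obs, sim), "mbe": mbe(obs, sim)}


def run_treatment(
    record,
    rates_row: dict,
    coeffs: ResponseCoefficients | None = None,
    days: int = DAYS_PER_YEAR,
    litter_init: str = "equilibrium",
) -> SimulationResult:
    """Hindcast one mesocosm treatment year with constant forcing.

    Parameters
    ----------
    record : TreatmentBudgetInputs
        Annual component means for the treatment (productivity, CH4, soil
        physical properties).
    rates_row : dict
        Treatment context: ``sal`` (ppt), ``wd_cm`` (maintained water depth),
        ``tr_ag``/``tr_bg`` (yr⁻¹ turnover multipliers).
    litter_init : {"equilibrium", "config"}
        ``equilibrium`` (default) starts the litter stocks at LS = LP/k for
        the treatment's regime and salinity, so decomposition initially
        balances litter production; ``config`` uses the ModelConfig defaults.
    """
    coeffs = coeffs or ResponseCoefficients.default()
    sal = float(rates_row["sal"])
    wd = float(rates_row["wd_cm"])
    tr_ag = float(rates_row["tr_ag"])
    tr_bg = float(rates_row["tr_bg"])
    regime = classify_regime(wd)
    lp_ag = record.anpp * tr_ag / DAYS_PER_YEAR
    lp_bg = record.bnpp * tr_bg / DAYS_PER_YEAR
    if litter_init == "equilibrium":
        kag = k_rate(sal, regime, "aboveground", coeffs)
        kbg = k_rate(sal, regime, "belowground", coeffs)
        ls_ag0 = lp_ag / kag if kag > 0 else 0.0
        ls_bg0 = lp_bg / kbg if kbg > 0 else 0.0
    elif litter_init == "config":
        ls_ag0, ls_bg0 = ModelConfig.ls_ag0, ModelConfig.ls_bg0
    else:
        raise InvalidInputError(f"unknown litter_init {litter_init!r}")
    config = ModelConfig(
        h0=1.5,
        rho_b=record.rho_b_field,
        alpha=record.alpha,
        f_c=record.f_c,
        tr_ag=tr_ag,
        tr_bg=tr_bg,
        ls_ag0=ls_ag0,
        ls_bg0=ls_bg0,
        pe0=0.0,
        eb=0.0,
    )
    ones = np.ones(days)
    forcing = ForcingSeries(
        anpp=ones * record.anpp / DAYS_PER_YEAR,
        bnpp=ones * record.bnpp / DAYS_PER_YEAR,
        f_ch4=ones * record.f_ch4 / DAYS_PER_YEAR,
        sal=ones * sal,
        wl=ones * wd,  # pe0 = 0, so WL == the maintained water depth
    )
    return simulate(config, forcing, coeffs)
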