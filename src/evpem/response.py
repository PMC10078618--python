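"""Salinity- and exposure-dependent response functions and their fitting.

The peat-surface exposure regime (submerged / exposed / extended-exposed,
split at water depths of 0 and -5 cm relative to the surface) selects which
empirical function of porewater salinity is used for the litter decomposition
rate constants (k_AG, k_BG, day^-1) and the salinity-driven net soil-material
change rate (ΔST, g m^-2 day^-1).  Above- and belowground net primary
productivity respond to salinity through a semi-logarithmic and a quadratic
curve, respectively.  This module also provides ordinary-least-squares fitting
of those functional forms and the Nash-Sutcliffe efficiency (NSE) and mean
bias error (MBE) used to evaluate them.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import statsmodels.api as sm
import yaml

from .exceptions import (
    ConfigurationError,
    FittingError,
    InvalidInputError,
    UndefinedMetricError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExposureRegime",
    "ResponseCoefficients",
    "FitResult",
    "classify_regime",
    "anpp_of_salinity",
    "bnpp_of_salinity",
    "k_rate",
    "delta_st_rate",
    "fit_response",
    "nse",
    "mbe",
]

#: Water-depth split (cm) between the exposed and extended-exposed regimes.
EXTENDED_EXPOSURE_DEPTH_CM = -5.0


class ExposureRegime(enum.Enum):
    """Hydrologic exposure state of the peat surface."""

    SUBMERGED = "submerged"
    EXPOSED = "exposed"
    EXTENDED_EXPOSED = "extended_exposed"


def classify_regime(wd: float) -> ExposureRegime:
    """Classify the exposure regime from water depth relative to the surface.

    Parameters
    ----------
    wd : float
        Water depth WD = WL - PE in cm; positive means standing water.

    Returns
    -------
    ExposureRegime
        ``SUBMERGED`` for WD >= 0, ``EXPOSED`` for -5 <= WD < 0 and
        ``EXTENDED_EXPOSED`` for WD < -5.  Boundaries belong to the wetter
        class (WD = 0 is submerged, WD = -5 is exposed).
    """
    if not math.isfinite(wd):
        raise InvalidInputError(f"water depth must be finite, got {wd!r}")
    if wd >= 0.0:
        return ExposureRegime.SUBMERGED
    if wd >= EXTENDED_EXPOSURE_DEPTH_CM:
        return ExposureRegime.EXPOSED
    return ExposureRegime.EXTENDED_EXPOSED


# ---------------------------------------------------------------------------
# Coefficient container


def _eval_quadratic(c: Mapping[str, float], x: float) -> float:
    return c["a"] * x * x + c["b"] * x + c["c"]


def _eval_semilog(c: Mapping[str, float], x: float) -> float:
    return c["intercept"] + c["slope"] * math.log(x)


def _eval_linear(c: Mapping[str, float], x: float) -> float:
    return c["intercept"] + c["slope"] * x


_BASIS_EVAL = {
    "quadratic": _eval_quadratic,
    "semilog": _eval_semilog,
    "linear": _eval_linear,
}


@dataclass(frozen=True)
class ResponseCoefficients:
    """Regime-keyed coefficient sets for the salinity response functions.

    ``k_ag`` and ``k_bg`` map each :class:`ExposureRegime` to a coefficient
    mapping with a ``basis`` key (``quadratic``: a·sal² + b·sal + c;
    ``semilog``: intercept + slope·ln sal; ``linear``: intercept + slope·sal).
    ``delta_st`` is analogous for the soil-material change rate; its fitted
    values are read as loss magnitudes when ``delta_st_loss_positive`` is set
    (the default), so the model term added to the peat stock is the negated
    fitted value.  ``anpp``/``bnpp`` hold the productivity-vs-salinity curves.
    """

    k_ag: Mapping[ExposureRegime, Mapping[str, float]]
    k_bg: Mapping[ExposureRegime, Mapping[str, float]]
    delta_st: Mapping[ExposureRegime, Mapping[str, float]]
    anpp: Mapping[str, float]
    bnpp: Mapping[str, float]
    delta_st_loss_positive: bool = True
    sal_floor: float = 0.1

    def __post_init__(self) -> None:
        if self.sal_floor <= 0:
            raise ConfigurationError("sal_floor must be positive")

    @classmethod
    def from_dict(cls, raw: Mapping) -> "ResponseCoefficients":
        def regime_map(section: Mapping) -> dict:
            out = {}
            for regime in ExposureRegime:
                if regime.value not in section:
                    raise ConfigurationError(
                        f"missing coefficient set for regime {regime.value!r}"
                    )
                entry = dict(section[regime.value])
                basis = entry.get("basis")
                if basis not in _BASIS_EVAL:
                    raise ConfigurationError(
                        f"unknown basis {basis!r} for regime {regime.value!r}"
                    )
                out[regime] = entry
            return out

        return cls(
            k_ag=regime_map(raw["k_ag"]),
            k_bg=regime_map(raw["k_bg"]),
            delta_st=regime_map(raw["delta_st"]),
            anpp=dict(raw["anpp"]),
            bnpp=dict(raw["bnpp"]),
            delta_st_loss_positive=(
                raw.get("delta_st_sign", "loss_positive") == "loss_positive"
            ),
            sal_floor=float(raw.get("sal_floor", 0.1)),
        )

    @classmethod
    def from_yaml(cls, path) -> "ResponseCoefficients":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ResponseCoefficients":
        """The bundled coefficient set (fitted response curves)."""
        ref = resources.files("evpem.data").joinpath("coefficients.yaml")
        return cls.from_dict(yaml.safe_load(ref.read_text(encoding="utf-8")))


def _floored_salinity(sal: float, sal_floor: float) -> float:
    if not math.isfinite(sal) or sal < 0:
        raise InvalidInputError(f"salinity must be finite and >= 0, got {sal!r}")
    return max(sal, sal_floor)


def _clamp_rate(value: float, what: str, sal: float) -> float:
    if value < 0.0:
        logger.debug("%s evaluated negative (%.3g) at sal=%.3g ppt; clamped to 0",
                     what, value, sal)
        return 0.0
    return value


def anpp_of_salinity(sal: float, coeffs: ResponseCoefficients | None = None) -> float:
    """Aboveground net primary productivity (gC m^-2 yr^-1) at a salinity.

    Semi-logarithmic decline with salinity, clamped at zero from below
    (the curve crosses zero near 51 ppt, well outside the fitted range).
    """
    coeffs = coeffs or ResponseCoefficients.default()
    if sal <= 0:
        raise InvalidInputError(f"salinity must be positive, got {sal!r}")
    s = _floored_salinity(sal, coeffs.sal_floor)
    value = _eval_semilog(coeffs.anpp, s)
    return _clamp_rate(value, "ANPP", s)


def bnpp_of_salinity(sal: float, coeffs: ResponseCoefficients | None = None) -> float:
    """Belowground net primary productivity (gC m^-2 yr^-1) at a salinity.

    Quadratic in salinity with a shallow maximum near 4.4 ppt, clamped at
    zero from below (negative beyond ~20 ppt).
    """
    coeffs = coeffs or ResponseCoefficients.default()
    if sal < 0:
        raise InvalidInputError(f"salinity must be >= 0, got {sal!r}")
    value = _eval_quadratic(coeffs.bnpp, sal)
    return _clamp_rate(value, "BNPP", sal)


def k_rate(
    sal: float,
    regime: ExposureRegime,
    which: str,
    coeffs: ResponseCoefficients | None = None,
) -> float:
    """Fractional litter decomposition rate (day^-1) for one litter pool.

    Parameters
    ----------
    sal : float
        Porewater salinity, ppt (floored at ``coeffs.sal_floor`` before any
        logarithm).
    regime : ExposureRegime
        Current exposure regime; selects the fitted functional form
        (quadratic when submerged, semi-logarithmic otherwise).
    which : {"aboveground", "belowground"}
        Which litter pool's rate to evaluate.

    Negative evaluations (extrapolation artefacts) are clamped to zero with a
    logged warning.
    """
    coeffs = coeffs or ResponseCoefficients.default()
    if which == "aboveground":
        table = coeffs.k_ag
    elif which == "belowground":
        table = coeffs.k_bg
    else:
        raise InvalidInputError(f"which must be 'aboveground' or 'belowground', got {which!r}")
    try:
        entry = table[regime]
    except KeyError as exc:  # pragma: no cover - guarded by from_dict
        raise ConfigurationError(f"no k coefficients for regime {regime}") from exc
    s = _floored_salinity(sal, coeffs.sal_floor)
    value = _BASIS_EVAL[entry["basis"]](entry, s)
    return _clamp_rate(value, f"k_{which[:2].upper()} ({regime.value})", s)


def delta_st_rate(
    sal: float,
    regime: ExposureRegime,
    coeffs: ResponseCoefficients | None = None,
) -> float:
    """Salinity-driven net soil-material change term (g m^-2 day^-1).

    The fitted curves quantify the loss magnitude of soil material as a
    function of salinity for each regime.  With the default loss-positive
    orientation the returned model term is the *negated* fitted value, so a
    negative return means soil loss and a positive return means gain.
    """
    coeffs = coeffs or ResponseCoefficients.default()
    try:
        entry = coeffs.delta_st[regime]
    except KeyError as exc:  # pragma: no cover
        raise ConfigurationError(f"no delta_st coefficients for regime {regime}") from exc
    s = _floored_salinity(sal, coeffs.sal_floor)
    fitted = _BASIS_EVAL[entry["basis"]](entry, s)
    return -fitted if coeffs.delta_st_loss_positive else fitted


# ---------------------------------------------------------------------------
# Fitting and evaluation metrics


@dataclass(frozen=True)
class FitResult:
    """Least-squares fit of a salinity response curve."""

    coefficients: dict
    standard_errors: dict
    nse: float
    mbe: float
    n: int
    functional_form: str
    fitted: np.ndarray = field(repr=False, default=None)


_FORM_NAMES = {
    "quadratic": ("a", "b", "c"),
    "semilog": ("slope", "intercept"),
    "linear": ("slope", "intercept"),
}


def _design_matrix(sal: np.ndarray, form: str) -> np.ndarray:
    if form == "quadratic":
        return np.column_stack([sal**2, sal, np.ones_like(sal)])
    if form == "semilog":
        if np.any(sal <= 0):
            raise InvalidInputError("semilog fit requires strictly positive salinities")
        return np.column_stack([np.log(sal), np.ones_like(sal)])
    if form == "linear":
        return np.column_stack([sal, np.ones_like(sal)])
    raise InvalidInputError(f"unknown functional form {form!r}")


def fit_response(
    sal_obs: Sequence[float],
    y_obs: Sequence[float],
    form: str,
) -> FitResult:
    """Fit a response curve to observations by ordinary least squares.

    Parameters
    ----------
    sal_obs, y_obs : sequence of float
        Paired salinity (ppt) and response observations.
    form : {"quadratic", "semilog", "linear"}
        Basis to regress on: ``a·sal² + b·sal + c``, ``slope·ln(sal) +
        intercept`` or ``slope·sal + intercept``.

    Returns
    -------
    FitResult
        Coefficients with standard errors plus NSE and MBE of the fit.
    """
    sal = np.asarray(sal_obs, dtype=float)
    y = np.asarray(y_obs, dtype=float)
    if sal.shape != y.shape or sal.ndim != 1:
        raise InvalidInputError("sal_obs and y_obs must be 1-d and the same length")
    names = _FORM_NAMES[form] if form in _FORM_NAMES else None
    if names is None:
        raise InvalidInputError(f"unknown functional form {form!r}")
    if sal.size < len(names):
        raise InvalidInputError(
            f"need at least {len(names)} observations for a {form} fit, got {sal.size}"
        )
    design = _design_matrix(sal, form)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise FittingError(f"rank-deficient design for {form} fit")
    model = sm.OLS(y, design).fit()
    fitted = np.asarray(model.fittedvalues, dtype=float)
    try:
        fit_nse = nse(y, fitted)
    except UndefinedMetricError:
        fit_nse = math.nan
    return FitResult(
        coefficients=dict(zip(names, model.params)),
        standard_errors=dict(zip(names, model.bse)),
        nse=fit_nse,
        mbe=mbe(y, fitted),
        n=int(sal.size),
        functional_form=form,
        fitted=fitted,
    )


def nse(obs: Sequence[float], sim: Sequence[float]) -> float:
    """Nash-Sutcliffe efficiency: 1 - Σ(obs-sim)² / Σ(obs-mean(obs))².

    1 is a perfect match, 0 matches the mean predictor, negative is worse
    than the mean predictor.
    """
    o = np.asarray(obs, dtype=float)
    s = np.asarray(sim, dtype=float)
    if o.shape != s.shape or o.size == 0:
        raise InvalidInputError("obs and sim must be equal-length, non-empty vectors")
    denom = float(np.sum((o - o.mean()) ** 2))
    if denom == 0.0:
        raise UndefinedMetricError("NSE undefined: observations are all identical")
    return 1.0 - float(np.sum((o - s) ** 2)) / denom


def mbe(obs: Sequence[float], sim: Sequence[float]) -> float:
    """Mean bias error: mean of (obs - sim), in the units of ``obs``."""
    o = np.asarray(obs, dtype=float)
    s = np.asarray(sim, dtype=float)
    if o.shape != s.shape or o.size == 0:
        raise InvalidInputError("obs and sim must be equal-length, non-empty vectors")
    return float(np.mean(o - s))
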