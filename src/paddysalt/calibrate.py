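"""Genotype parameter estimation.

Two fitting problems:

* the logistic salt-stress parameters (a, b) from greenhouse dose-response
  curves of leaf transpiration or photosynthesis versus EC, by nonlinear
  least squares; optionally with a single slope ``a`` shared between the two
  processes (the slope is often indistinguishable between them while the
  50%-loss EC ``b`` differs clearly);
* vegetative and reproductive development rates from observed phenology
  dates (transplanting, flowering, maturity) and the season's weather, as
  reciprocals of the accumulated thermal time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .crop import thermal_time
from .salinity import stress_factor


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class ResponseCurve:
    """Greenhouse dose-response points: (EC dS/m, relative rate)."""

    ec: tuple
    rate: tuple
    process: str = "transpiration"

    def __post_init__(self) -> None:
        if len(self.ec) != len(self.rate):
            raise CalibrationError("ec and rate must have equal length")
        if len(self.ec) < 4:
            raise CalibrationError("need at least 4 response points to fit")
        if np.any(np.asarray(self.ec, dtype=float) < 0):
            raise CalibrationError("EC values must be non-negative")

    def normalized(self) -> "ResponseCurve":
        """Rates divided by the mean rate at the lowest EC (the control)."""
        ec = np.asarray(self.ec, dtype=float)
        rate = np.asarray(self.rate, dtype=float)
        control = rate[ec == ec.min()].mean()
        if control <= 0:
            raise CalibrationError("control-rate mean is not positive")
        return ResponseCurve(tuple(ec), tuple(rate / control), self.process)


@dataclass(frozen=True)
class StressFit:
    a: float
    b: float
    converged: bool
    residual_sd: float


def _logistic(ec, a, b):
    return 1.0 / (1.0 + np.exp(a * (ec - b)))


def fit_stress_params(
    curve: ResponseCurve, init: tuple | None = None, normalize: bool = False
) -> StressFit:
    """Fit the logistic stress factor to a dose-response curve.

    Plain (unweighted) nonlinear least squares on FS(ec; a, b) with both
    parameters bounded positive.  Default start: a = 0.2, b = median EC.
    A flat or otherwise unidentifiable curve is returned with
    ``converged=False`` rather than raising.
    """
    if normalize:
        curve = curve.normalized()
    ec = np.asarray(curve.ec, dtype=float)
    rate = np.asarray(curve.rate, dtype=float)
    if np.ptp(rate) < 1e-9:
        # a flat curve carries no information about the inflection point
        return StressFit(a=np.nan, b=np.nan, converged=False, residual_sd=0.0)
    p0 = init if init is not None else (0.2, float(np.median(ec)))
    try:
        popt, pcov = optimize.curve_fit(
            _logistic,
            ec,
            rate,
            p0=p0,
            bounds=([1e-9, 1e-9], [np.inf, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, optimize.OptimizeWarning):
        return StressFit(a=np.nan, b=np.nan, converged=False, residual_sd=np.nan)
    a, b = float(popt[0]), float(popt[1])
    resid = rate - _logistic(ec, a, b)
    residual_sd = float(np.sqrt(np.mean(resid**2)))
    identified = bool(
        np.all(np.isfinite(pcov)) and a > 1e-8 and 1e-8 < b < 10 * max(ec.max(), 1.0)
    )
    return StressFit(a=a, b=b, converged=identified, residual_sd=residual_sd)


@dataclass(frozen=True)
class SharedSlopeFit:
    a: float
    b_pn: float
    b_tr: float
    converged: bool
    residual_sd: float


def fit_shared_slope(
    curve_pn: ResponseCurve, curve_tr: ResponseCurve, init: tuple | None = None
) -> SharedSlopeFit:
    """Joint fit of both process curves with one shared slope ``a``.

    Stacks the residuals of the photosynthesis and transpiration curves and
    solves for (a, b_pn, b_tr) simultaneously.
    """
    ec_pn = np.asarray(curve_pn.ec, dtype=float)
    r_pn = np.asarray(curve_pn.rate, dtype=float)
    ec_tr = np.asarray(curve_tr.ec, dtype=float)
    r_tr = np.asarray(curve_tr.rate, dtype=float)

    def residuals(p):
        a, b_pn, b_tr = p
        return np.concatenate(
            [r_pn - _logistic(ec_pn, a, b_pn), r_tr - _logistic(ec_tr, a, b_tr)]
        )

    p0 = init if init is not None else (
        0.2,
        float(np.median(ec_pn)),
        float(np.median(ec_tr)),
    )
    sol = optimize.least_squares(
        residuals, p0, bounds=([1e-9] * 3, [np.inf] * 3), max_nfev=10000
    )
    resid_sd = float(np.sqrt(np.mean(sol.fun**2)))
    return SharedSlopeFit(
        a=float(sol.x[0]),
        b_pn=float(sol.x[1]),
        b_tr=float(sol.x[2]),
        converged=bool(sol.success),
        residual_sd=resid_sd,
    )


def derive_dev_rates(
    transplant_day: int,
    flowering_day: int,
    maturity_day: int,
    weather: pd.DataFrame,
    tbase: float,
) -> tuple[float, float]:
    """Development rates (per degC-day) from observed phenology dates.

    DVR_veg is the reciprocal of the thermal time accumulated from
    transplanting to flowering, DVR_rep from flowering to maturity; a
    season simulated with these rates reproduces the observed dates to
    within a day.
    """
    if not (0 <= transplant_day < flowering_day < maturity_day):
        raise CalibrationError(
            "need transplant < flowering < maturity day indices, got "
            f"{transplant_day}, {flowering_day}, {maturity_day}"
        )
    if maturity_day > len(weather):
        raise CalibrationError("phenology dates extend beyond the weather table")
    tmin = weather["tmin"].to_numpy(dtype=float)
    tmax = weather["tmax"].to_numpy(dtype=float)
    tt = np.array(
        [thermal_time(lo, hi, tbase) for lo, hi in zip(tmin, tmax)]
    )
    tt_veg = float(tt[transplant_day:flowering_day].sum())
    tt_rep = float(tt[flowering_day:maturity_day].sum())
    if tt_veg <= 0 or tt_rep <= 0:
        raise CalibrationError("zero accumulated thermal time between stage dates")
    return 1.0 / tt_veg, 1.0 / tt_rep
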