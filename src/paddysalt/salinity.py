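"""Salinity primitives: EC conversions and the logistic salt-stress factor.

Soil salinity is carried everywhere as electrical conductivity of the soil
solution (EC, dS/m).  Three conversions hang off it:

* osmotic tension of the soil solution, proportional to EC
  (``OSKPA = 40.55 * EC`` kPa);
* EC from the average chloride concentration of the root-zone solution
  (``EC = [Cl] / 640`` with [Cl] in ppm);
* the two-parameter logistic stress factor
  ``FS = 1 / (1 + exp(a * (EC - b)))`` that multiplies daily photosynthesis
  and transpiration.  ``b`` is the EC at which half the process rate is lost
  (tolerance); ``a`` is the slope at that inflection point (resilience —
  smaller ``a`` means a more gradual decline).

Note that FS(0) < 1 by construction: even at zero salinity the logistic does
not reach unity.  The faithful behaviour is the default; pass
``normalize=True`` for the rescaled variant FS(EC)/FS(0) that gives an exact
unit factor under fresh water.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class SalinityDomainError(ValueError):
    """Raised when an EC, concentration or parameter is outside its domain."""


@dataclass(frozen=True)
class ConversionConstants:
    """Unit-bridge constants of the salinity loop.

    osmotic_kpa_per_dsm
        Osmotic tension of the soil solution per unit EC (kPa per dS/m).
    chloride_ppm_per_dsm
        Chloride concentration (ppm, i.e. mg/L) corresponding to 1 dS/m.
        Its inverse converts root-zone chloride to EC, and forward it sets
        the chloride load of saline irrigation water.
    """

    osmotic_kpa_per_dsm: float = 40.55
    chloride_ppm_per_dsm: float = 640.0

    def __post_init__(self) -> None:
        if self.osmotic_kpa_per_dsm <= 0 or self.chloride_ppm_per_dsm <= 0:
            raise SalinityDomainError("conversion constants must be strictly positive")


DEFAULT_CONSTANTS = ConversionConstants()


@dataclass(frozen=True)
class SalinityParams:
    """Genotype tolerance parameters of the logistic stress factor.

    ``a_pn``/``b_pn`` act on photosynthesis, ``a_tr``/``b_tr`` on
    transpiration.  ``b`` values are in dS/m; ``a`` values are slopes per
    dS/m.  All four must be strictly positive.
    """

    genotype: str
    a_pn: float
    b_pn: float
    a_tr: float
    b_tr: float

    def __post_init__(self) -> None:
        for name in ("a_pn", "b_pn", "a_tr", "b_tr"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise SalinityDomainError(
                    f"{name} must be finite and strictly positive, got {v!r}"
                )

    def fs_pn(self, ec, *, normalize: bool = False):
        """Stress factor on photosynthesis at soil EC (dS/m)."""
        return stress_factor(ec, self.a_pn, self.b_pn, normalize=normalize)

    def fs_tr(self, ec, *, normalize: bool = False):
        """Stress factor on transpiration at soil EC (dS/m)."""
        return stress_factor(ec, self.a_tr, self.b_tr, normalize=normalize)

    def replace(self, **changes) -> "SalinityParams":
        """Return a copy with some parameters replaced (validates anew)."""
        fields = dict(
            genotype=self.genotype,
            a_pn=self.a_pn,
            b_pn=self.b_pn,
            a_tr=self.a_tr,
            b_tr=self.b_tr,
        )
        fields.update(changes)
        return SalinityParams(**fields)


def stress_factor(ec, a: float, b: float, *, normalize: bool = False):
    """Logistic salt-stress factor FS = 1 / (1 + exp(a * (EC - b))).

    Strictly decreasing in ``ec``; equals 0.5 exactly at ``ec == b``.
    With ``normalize=True`` the value is divided by FS(0) so fresh water
    gives exactly 1.

    Parameters
    ----------
    ec : float or array-like
        Soil solution electrical conductivity, dS/m, >= 0.
    a, b : float
        Slope at the inflection point (per dS/m) and EC of 50% loss (dS/m),
        both strictly positive.
    """
    ec = np.asarray(ec, dtype=float)
    if np.any(ec < 0):
        raise SalinityDomainError("ec must be non-negative")
    if a <= 0 or b <= 0 or not np.isfinite(a) or not np.isfinite(b):
        raise SalinityDomainError("a and b must be finite and strictly positive")
    # log-sum-exp form of 1/(1+exp(x)): stable for large a*(ec-b)
    fs = np.exp(-np.logaddexp(0.0, a * (ec - b)))
    if normalize:
        fs = fs * (1.0 + np.exp(-a * b))
    return fs if fs.ndim else float(fs)


def osmotic_tension(ec, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Osmotic tension (kPa, positive) of the soil solution at EC (dS/m).

    Represented as a positive tension so it adds directly onto matric
    tension; no signed-potential bookkeeping.
    """
    ec = np.asarray(ec, dtype=float)
    if np.any(ec < 0):
        raise SalinityDomainError("ec must be non-negative")
    t = constants.osmotic_kpa_per_dsm * ec
    return t if t.ndim else float(t)


def ec_from_chloride(conc_ppm, constants: ConversionConstants = DEFAULT_CONSTANTS):
    """Soil solution EC (dS/m) from chloride concentration (ppm)."""
    conc = np.asarray(conc_ppm, dtype=float)
    if np.any(conc < 0):
        raise SalinityDomainError("chloride concentration must be non-negative")
    ec = conc / constants.chloride_ppm_per_dsm
    return ec if ec.ndim else float(ec)


def layer_chloride_conc(mass_kg_ha: float, water_mm: float) -> float:
    """Solution chloride concentration (ppm) of a soil compartment.

    1 kg/ha dissolved in 1 mm of water over 1 ha (10^4 L) is 100 mg/L,
    hence ``conc = 100 * mass / water``.
    """
    if water_mm <= 0:
        raise SalinityDomainError(
            f"compartment water must be positive, got {water_mm!r} mm"
        )
    if mass_kg_ha < 0:
        raise SalinityDomainError("chloride mass must be non-negative")
    return 100.0 * mass_kg_ha / water_mm


@dataclass(frozen=True)
class ECMeasurementSeries:
    """Sparse soil-EC measurements as (day-index, EC dS/m) pairs.

    Days are 0-based from transplanting, strictly increasing; EC >= 0.
    """

    days: tuple
    ec: tuple

    def __post_init__(self) -> None:
        if len(self.days) == 0:
            raise SalinityDomainError("EC measurement series is empty")
        if len(self.days) != len(self.ec):
            raise SalinityDomainError("days and ec must have equal length")
        d = np.asarray(self.days, dtype=float)
        if np.any(np.diff(d) <= 0):
            raise SalinityDomainError("measurement days must be strictly increasing")
        if np.any(np.asarray(self.ec, dtype=float) < 0):
            raise SalinityDomainError("EC measurements must be non-negative")

    @classmethod
    def from_pairs(cls, pairs) -> "ECMeasurementSeries":
        pairs = list(pairs)
        return cls(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs))


def interpolate_daily_ec(series: ECMeasurementSeries, n_days: int) -> np.ndarray:
    """Daily EC vector of length ``n_days`` from sparse measurements.

    Piecewise linear between measurements; held constant at the first/last
    measured value outside the measured span (EC is never extrapolated
    below zero or beyond the last reading).
    """
    if n_days < 1:
        raise SalinityDomainError("n_days must be >= 1")
    days = np.asarray(series.days, dtype=float)
    ec = np.asarray(series.ec, dtype=float)
    out = np.interp(np.arange(n_days, dtype=float), days, ec)
    return out
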