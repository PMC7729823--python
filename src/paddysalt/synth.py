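"""Seeded synthetic fixtures: weather, greenhouse curves, field observations.

Every generator is a pure function of (profile/parameters, seed): the same
seed reproduces the same table bit-for-bit, and no external data are needed
anywhere in the package.  The weather generator emulates a humid tropical
lowland station (distinct wet/dry seasonality, mean daily maxima around
28-32 degC, 15-22 MJ/m2 radiation); the greenhouse generator draws
dose-response points from the logistic stress factor over the 0-20 dS/m
gradient spanning light (4), mild (8) and severe (>12 dS/m) stress; the
field-observation generator subsamples a simulated season at the
conventional sampling stages with multiplicative log-normal replicate noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibrate import ResponseCurve
from .crop import SeasonResult
from .salinity import SalinityParams, stress_factor
from .soil import IrrigationEvent


@dataclass(frozen=True)
class WeatherProfile:
    """Climatology of the synthetic station (annual sinusoid + noise)."""

    name: str = "tropical-lowland"
    tmax_mean: float = 30.0
    tmax_amp: float = 1.5
    tmin_mean: float = 23.5
    tmin_amp: float = 1.0
    rad_mean: float = 18.0
    rad_amp: float = 4.0
    temp_sd: float = 1.0
    rad_sd: float = 2.5
    rain_prob: float = 0.35
    rain_mean_mm: float = 12.0

    def __post_init__(self) -> None:
        if not (-10 <= self.tmin_mean <= self.tmax_mean <= 45):
            raise ValueError("temperature means outside physical bounds")
        if not (0 <= self.rad_mean <= 35):
            raise ValueError("radiation mean outside physical bounds")
        if not (0 <= self.rain_prob <= 1):
            raise ValueError("rain probability must be in [0, 1]")


TROPICAL = WeatherProfile()


def generate_weather(
    profile: WeatherProfile = TROPICAL,
    n_years: int = 1,
    seed: int = 0,
    start: str = "2012-01-01",
) -> pd.DataFrame:
    """Daily weather table: date, tmin, tmax, rad, rain (and year).

    Seasonal sinusoid (peak mid-year) plus Gaussian noise for temperatures
    and radiation; rainfall from seeded wet-day draws with exponential
    depths.  ``tmin <= tmax`` and non-negative radiation/rain are enforced.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(seed)
    n = 365 * n_years
    doy = np.arange(n) % 365
    phase = 2 * np.pi * (doy - 120) / 365.0
    season = np.cos(phase)

    tmax = profile.tmax_mean + profile.tmax_amp * season + rng.normal(
        0, profile.temp_sd, n
    )
    tmin = profile.tmin_mean + profile.tmin_amp * season + rng.normal(
        0, profile.temp_sd, n
    )
    tmin = np.minimum(tmin, tmax - 0.5)
    rad = np.clip(
        profile.rad_mean + profile.rad_amp * season + rng.normal(0, profile.rad_sd, n),
        0.5,
        35.0,
    )
    wet = rng.random(n) < profile.rain_prob
    rain = np.where(
        wet, rng.exponential(max(profile.rain_mean_mm, 1e-12), n), 0.0
    )
    if profile.rain_mean_mm == 0 or profile.rain_prob == 0:
        rain = np.zeros(n)

    dates = pd.date_range(start, periods=n, freq="D")
    return pd.DataFrame(
        {
            "date": dates,
            "tmin": np.round(tmin, 2),
            "tmax": np.round(tmax, 2),
            "rad": np.round(rad, 2),
            "rain": np.round(rain, 2),
            "year": dates.year[0] + np.arange(n) // 365,
        }
    )


def generate_greenhouse_response(
    params: SalinityParams,
    process: str = "transpiration",
    n_points: int = 12,
    noise_cv: float = 0.05,
    seed: int = 0,
) -> ResponseCurve:
    """Dose-response curve of relative rate vs EC over a 0-20 dS/m gradient.

    Points lie on the genotype's logistic stress curve, perturbed by
    multiplicative noise with the given coefficient of variation
    (``noise_cv=0`` gives exact curve points).
    """
    if n_points < 4:
        raise ValueError("need at least 4 points")
    if process not in ("transpiration", "photosynthesis"):
        raise ValueError(f"unknown process {process!r}")
    rng = np.random.default_rng(seed)
    ec = np.linspace(0.0, 20.0, n_points)
    a = params.a_tr if process == "transpiration" else params.a_pn
    b = params.b_tr if process == "transpiration" else params.b_pn
    truth = stress_factor(ec, a, b)
    rate = np.clip(truth * (1.0 + noise_cv * rng.standard_normal(n_points)), 0.0, None)
    return ResponseCurve(tuple(ec), tuple(rate), process)


SAMPLING_STAGES = ("28DAS", "42DAS", "flowering", "grain_filling", "maturity")


def _stage_days(season: SeasonResult) -> dict:
    """Day index of each conventional sampling stage in a simulated season."""
    daily = season.daily
    dvs = daily["dvs"].to_numpy()

    def first_day_at(level):
        idx = np.nonzero(dvs >= level)[0]
        return int(daily["day"].iloc[idx[0]]) if len(idx) else season.maturity_day

    return {
        "28DAS": min(28, season.maturity_day),
        "42DAS": min(42, season.maturity_day),
        "flowering": first_day_at(1.0),
        "grain_filling": first_day_at(1.5),
        "maturity": season.maturity_day,
    }


def generate_field_observations(
    season: SeasonResult,
    cv: float = 0.1,
    seed: int = 0,
    n_reps: int = 3,
) -> pd.DataFrame:
    """Noisy pseudo-observations of a simulated season.

    WAGT and LAI at the five conventional sampling stages, yield at
    maturity, each with ``n_reps`` replicates carrying multiplicative
    log-normal noise of the given CV (``cv=0`` reproduces the simulated
    truth exactly).  Columns: variable, stage, day, rep, value, truth;
    per-point replicate SDs follow from a groupby.
    """
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    stage_days = _stage_days(season)
    daily = season.daily.set_index("day")

    rows = []

    def emit(variable, stage, day, truth):
        for rep in range(1, n_reps + 1):
            noise = (
                np.exp(sigma * rng.standard_normal() - 0.5 * sigma**2)
                if cv > 0
                else 1.0
            )
            rows.append(
                dict(
                    variable=variable,
                    stage=stage,
                    day=day,
                    rep=rep,
                    value=truth * noise,
                    truth=truth,
                )
            )

    for stage in SAMPLING_STAGES:
        day = stage_days[stage]
        emit("wagt", stage, day, float(daily.loc[day, "wagt"]))
        emit("lai", stage, day, float(daily.loc[day, "lai"]))
    emit("yield", "maturity", stage_days["maturity"], season.yield_kg_ha)

    return pd.DataFrame(rows)


def generate_irrigation_schedule(
    target_ec: float,
    interval_d: int = 3,
    depth_mm: float = 50.0,
    season_length_d: int = 110,
    start_day: int = 5,
    end_margin_d: int = 10,
) -> list:
    """Saline irrigation events at a regular interval.

    Events run from ``start_day`` after transplanting to ``end_margin_d``
    days before the end of the season, each applying ``depth_mm`` of water
    at ``target_ec`` dS/m (constant-salinity treatment).  Fresh-water
    control treatments simply pass a low ``target_ec`` (0.8-1.4 dS/m range).
    """
    if interval_d < 1:
        raise ValueError("interval must be >= 1 day")
    last_day = season_length_d - end_margin_d
    return [
        IrrigationEvent(day=d, depth_mm=depth_mm, ec_dsm=target_ec)
        for d in range(start_day, last_day, interval_d)
    ]
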