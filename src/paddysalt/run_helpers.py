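"""Season-runner factories for scenario studies.

A "runner" is a callable ``(salinity_params, level, year) -> SeasonResult``
handed to :func:`paddysalt.sensitivity.run_scenarios`.  The factory here
caches one synthetic weather table per year and imposes each salinity level
as a constant measured-EC pattern, so the annual soil-salinity dynamics are
identical across years and the only things varying over the grid are the
perturbed parameter, the level and the year's weather.
"""

from __future__ import annotations

import pandas as pd

from .crop import CropParams, SeasonResult, simulate_season
from .salinity import ECMeasurementSeries, SalinityParams
from .soil import Pond, SoilProfile, default_pond, default_profile
from .synth import TROPICAL, WeatherProfile, generate_weather


def constant_ec_runner(
    n_years: int = 2,
    seed: int = 0,
    season_days: int = 150,
    crop_params: CropParams | None = None,
    weather_profile: WeatherProfile = TROPICAL,
    soil: SoilProfile | None = None,
    pond: Pond | None = None,
    transplant_doy: int = 15,
):
    """Runner with per-year synthetic weather and constant-EC salinity levels.

    Each year's weather is drawn once from ``seed + year`` (so the set of
    environments is fixed for the whole grid) and each salinity level is a
    constant daily soil-EC series, the same pattern every year.
    """
    crop_params = crop_params if crop_params is not None else CropParams()
    weather_by_year = {}
    for year in range(n_years):
        table = generate_weather(weather_profile, n_years=1, seed=seed + year)
        weather_by_year[year] = table.iloc[
            transplant_doy : transplant_doy + season_days
        ].reset_index(drop=True)

    base_soil = soil if soil is not None else default_profile()
    base_pond = pond if pond is not None else default_pond()

    def runner(params: SalinityParams, level: float, year: int) -> SeasonResult:
        weather = weather_by_year[int(year)]
        series = ECMeasurementSeries((0,), (float(level),))
        return simulate_season(
            weather,
            base_soil,
            base_pond,
            crop_params,
            params,
            mode="measured",
            ec_series=series,
        )

    return runner
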