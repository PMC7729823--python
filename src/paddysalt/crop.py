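"""Daily rice growth loop with drought and salinity stress.

The engine is a deliberately compact, stage-driven canopy model in the
spirit of daily rice simulators: phenology advances with thermal time on a
development-stage (DVS) scale where 1 is flowering and 2 physiological
maturity; canopy assimilation uses a radiation-use-efficiency (RUE) core
with Beer-law light interception; assimilate is partitioned to leaf, stem
and panicle by a DVS-keyed table; LAI follows green-leaf biomass through the
specific leaf area.

Salinity acts exactly where the two-parameter logistic factor prescribes:
FS_tr multiplies the potential transpiration rate (together with the drought
factor computed from matric + osmotic tension), and FS_pn multiplies gross
assimilation together with PCEW, the ratio of actual to potential
transpiration.  Salinity effects on phenology are *not* modelled
mechanistically — per-treatment development rates are inputs, which is the
calibration convention this engine replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import soil as soil_mod
from .salinity import (
    ConversionConstants,
    DEFAULT_CONSTANTS,
    ECMeasurementSeries,
    SalinityParams,
    interpolate_daily_ec,
    osmotic_tension,
)
from .soil import IrrigationEvent, Pond, SoilProfile, irrigation_salt_load


class CropError(ValueError):
    pass


class IncompleteSeasonError(RuntimeError):
    """Weather ran out before the crop reached maturity."""


# DVS-keyed partitioning knots: (dvs, leaf, stem, panicle); fractions at
# each knot sum to 1 and are linearly interpolated between knots.
DEFAULT_PARTITION_TABLE = (
    (0.00, 0.55, 0.45, 0.00),
    (0.50, 0.50, 0.50, 0.00),
    (0.75, 0.30, 0.70, 0.00),
    (1.00, 0.00, 0.40, 0.60),
    (1.20, 0.00, 0.00, 1.00),
    (2.00, 0.00, 0.00, 1.00),
)


@dataclass(frozen=True)
class CropParams:
    """Genotype-and-management crop parameters (generic IR64-like indica).

    Units: temperatures degC, development rates per degC-day, RUE g/MJ of
    intercepted PAR, SLA ha/kg, depths mm, tensions kPa.
    """

    tbase: float = 8.0
    dvr_veg: float = 0.0008
    dvr_rep: float = 0.0015
    rue: float = 2.2
    k_ext: float = 0.6
    sla: float = 0.0022
    partition_table: tuple = DEFAULT_PARTITION_TABLE
    senescence_rate: float = 0.0125
    root_depth_init_mm: float = 150.0
    root_growth_mm_d: float = 10.0
    root_depth_max_mm: float = 400.0
    tau_low_kpa: float = 30.0
    tau_max_kpa: float = 1500.0
    init_leaf_kg_ha: float = 60.0
    init_stem_kg_ha: float = 40.0

    def __post_init__(self) -> None:
        if self.tau_low_kpa >= self.tau_max_kpa:
            raise CropError("need tau_low < tau_max")
        for name in ("dvr_veg", "dvr_rep", "rue", "k_ext", "sla", "senescence_rate"):
            if getattr(self, name) < 0:
                raise CropError(f"{name} must be non-negative")
        for knot in self.partition_table:
            if abs(sum(knot[1:]) - 1.0) > 1e-9:
                raise CropError(f"partition fractions at DVS {knot[0]} do not sum to 1")

    def replace(self, **changes) -> "CropParams":
        return replace(self, **changes)


@dataclass
class CropState:
    """Crop state carried between days.

    WAGT = green leaf + dead leaf + stem + panicle; WSO = panicle pool;
    LAI = SLA x green leaf biomass.
    """

    dvs: float = 0.0
    leaf_green_kg_ha: float = 0.0
    leaf_dead_kg_ha: float = 0.0
    stem_kg_ha: float = 0.0
    panicle_kg_ha: float = 0.0
    lai: float = 0.0
    root_depth_mm: float = 150.0
    cum_transpiration_mm: float = 0.0

    @property
    def wagt(self) -> float:
        return (
            self.leaf_green_kg_ha
            + self.leaf_dead_kg_ha
            + self.stem_kg_ha
            + self.panicle_kg_ha
        )

    @property
    def wso(self) -> float:
        return self.panicle_kg_ha

    @classmethod
    def at_transplanting(cls, params: CropParams) -> "CropState":
        return cls(
            leaf_green_kg_ha=params.init_leaf_kg_ha,
            stem_kg_ha=params.init_stem_kg_ha,
            lai=params.sla * params.init_leaf_kg_ha,
            root_depth_mm=params.root_depth_init_mm,
        )


@dataclass(frozen=True)
class DailyWeather:
    tmin: float
    tmax: float
    rad: float  # MJ/m2/d solar radiation
    rain: float  # mm

    def __post_init__(self) -> None:
        if self.tmin > self.tmax:
            raise CropError(f"tmin {self.tmin} exceeds tmax {self.tmax}")
        if self.rad < 0 or self.rain < 0:
            raise CropError("radiation and rain must be non-negative")


def thermal_time(tmin: float, tmax: float, tbase: float) -> float:
    """Daily thermal time (degC-day) above the base temperature."""
    if tmin > tmax:
        raise CropError("tmin must not exceed tmax")
    return max(0.0, 0.5 * (tmin + tmax) - tbase)


def advance_dvs(dvs: float, tt: float, params: CropParams) -> float:
    """Advance DVS by one day's thermal time, splitting at flowering.

    Vegetative rate applies below DVS 1, reproductive above; a day that
    crosses 1.0 spends the remaining thermal time at the reproductive rate.
    Capped at 2 (maturity).
    """
    if tt < 0:
        raise CropError("thermal time must be non-negative")
    if dvs < 1.0:
        if params.dvr_veg <= 0:
            return dvs
        tt_to_flowering = (1.0 - dvs) / params.dvr_veg
        if tt <= tt_to_flowering:
            return dvs + params.dvr_veg * tt
        dvs = 1.0
        tt -= tt_to_flowering
    return min(2.0, dvs + params.dvr_rep * tt)


def reference_et(weather: DailyWeather) -> float:
    """Priestley-Taylor reference evapotranspiration (mm/d).

    alpha = 1.26, net radiation taken as 0.75 x incoming solar, latent heat
    2.45 MJ/kg, psychrometric constant 0.066 kPa/degC, saturation-slope from
    the Tetens form at the daily mean temperature.
    """
    tmean = 0.5 * (weather.tmin + weather.tmax)
    es = 0.6108 * math.exp(17.27 * tmean / (tmean + 237.3))
    slope = 4098.0 * es / (tmean + 237.3) ** 2
    gamma = 0.066
    rn = 0.75 * weather.rad
    return max(0.0, 1.26 * slope / (slope + gamma) * rn / 2.45)


def drought_factor(effective_tension_kpa: float, params: CropParams) -> float:
    """Transpiration reduction factor from total (matric + osmotic) tension.

    1 below ``tau_low``, linear to 0 at ``tau_max``, clamped to [0, 1].
    """
    if effective_tension_kpa < 0:
        raise CropError("tension must be non-negative")
    if effective_tension_kpa <= params.tau_low_kpa:
        return 1.0
    if effective_tension_kpa >= params.tau_max_kpa:
        return 0.0
    return (params.tau_max_kpa - effective_tension_kpa) / (
        params.tau_max_kpa - params.tau_low_kpa
    )


def partition_fractions(dvs: float, table=DEFAULT_PARTITION_TABLE):
    """(leaf, stem, panicle) fractions at a DVS, linearly interpolated."""
    knots = np.asarray(table, dtype=float)
    dvs = min(max(dvs, knots[0, 0]), knots[-1, 0])
    leaf = float(np.interp(dvs, knots[:, 0], knots[:, 1]))
    stem = float(np.interp(dvs, knots[:, 0], knots[:, 2]))
    pan = float(np.interp(dvs, knots[:, 0], knots[:, 3]))
    s = leaf + stem + pan
    return leaf / s, stem / s, pan / s


@dataclass
class DailyGrowthResult:
    growth_kg_ha: float
    t_pot_mm: float
    t_act_mm: float
    pcew: float


def daily_growth(
    state: CropState,
    weather: DailyWeather,
    fs_pn: float,
    fs_tr: float,
    drought: float,
    params: CropParams,
    water_supply_mm: float | None = None,
) -> DailyGrowthResult:
    """One day of canopy assimilation, partitioning and senescence.

    Potential transpiration is the canopy-intercepted share of reference ET;
    actual transpiration applies the drought and salinity factors and is
    capped by the soil supply.  Gross growth is
    ``RUE x 0.5 Rs x (1 - exp(-k LAI)) x FS_pn x PCEW`` (0.5 converts solar
    to PAR; x10 converts g/m2 to kg/ha), partitioned by the DVS table.
    Mutates ``state`` and returns the day's fluxes.
    """
    fint = 1.0 - math.exp(-params.k_ext * state.lai)
    et0 = reference_et(weather)
    t_pot = et0 * fint
    t_act = t_pot * drought * fs_tr
    if water_supply_mm is not None:
        t_act = min(t_act, water_supply_mm)
    pcew = t_act / t_pot if t_pot > 0 else 1.0

    growth = params.rue * 0.5 * weather.rad * fint * fs_pn * pcew * 10.0

    f_leaf, f_stem, f_pan = partition_fractions(state.dvs, params.partition_table)
    state.leaf_green_kg_ha += growth * f_leaf
    state.stem_kg_ha += growth * f_stem
    state.panicle_kg_ha += growth * f_pan

    if state.dvs >= 1.0:
        sen = state.leaf_green_kg_ha * params.senescence_rate
        state.leaf_green_kg_ha -= sen
        state.leaf_dead_kg_ha += sen

    state.lai = params.sla * state.leaf_green_kg_ha
    state.cum_transpiration_mm += t_act
    return DailyGrowthResult(growth_kg_ha=growth, t_pot_mm=t_pot, t_act_mm=t_act, pcew=pcew)


@dataclass
class SeasonResult:
    """Daily trajectories and end-of-season summaries of one run."""

    daily: pd.DataFrame
    yield_kg_ha: float
    total_transpiration_mm: float
    maturity_day: int
    genotype: str

    @property
    def final_wagt(self) -> float:
        return float(self.daily["wagt"].iloc[-1])


def simulate_season(
    weather: pd.DataFrame,
    soil: SoilProfile,
    pond: Pond,
    crop_params: CropParams,
    salinity_params: SalinityParams,
    mode: str = "measured",
    ec_series: ECMeasurementSeries | None = None,
    schedule: list | None = None,
    constants: ConversionConstants = DEFAULT_CONSTANTS,
    normalize_fs: bool = False,
    auto_flood_depth_mm: float = 30.0,
    max_ec_manager: float | None = None,
    manager_fresh_ec: float = 1.0,
) -> SeasonResult:
    """Run the daily loop from transplanting to maturity (DVS = 2).

    Parameters
    ----------
    weather : DataFrame with columns tmin, tmax, rad, rain, one row per day
        from transplanting.  Must cover the whole season or an
        :class:`IncompleteSeasonError` is raised.
    mode : 'measured' or 'simulated'
        'measured' takes the daily soil EC from ``ec_series`` (sparse
        measurements, linearly interpolated); 'simulated' derives it from the
        chloride state of the soil profile driven by the irrigation
        ``schedule`` salt loads.
    schedule : list of IrrigationEvent, optional
        If omitted, the pond is topped up daily to ``auto_flood_depth_mm``
        with fresh water (continuous flooding).
    max_ec_manager : float, optional
        Management rule: when the day's root-zone EC is at or above this
        threshold, saline irrigation is replaced by water at
        ``manager_fresh_ec`` (suspended salt application).  Off by default.

    The run is fully deterministic: identical inputs give identical results.
    """
    if mode not in ("measured", "simulated"):
        raise CropError(f"unknown mode {mode!r}")
    n_days = len(weather)
    if n_days == 0:
        raise CropError("empty weather table")
    if mode == "measured":
        if ec_series is None:
            raise CropError("measured-EC mode requires an EC measurement series")
        daily_ec = interpolate_daily_ec(ec_series, n_days)

    events_by_day: dict[int, list] = {}
    if schedule is not None:
        for ev in schedule:
            events_by_day.setdefault(ev.day, []).append(ev)

    profile = soil.copy()
    pond = pond.copy()
    state = CropState.at_transplanting(crop_params)

    rows = []
    maturity_day = None
    tmin_a = weather["tmin"].to_numpy(dtype=float)
    tmax_a = weather["tmax"].to_numpy(dtype=float)
    rad_a = weather["rad"].to_numpy(dtype=float)
    rain_a = weather["rain"].to_numpy(dtype=float)

    for day in range(n_days):
        wx = DailyWeather(
            tmin=tmin_a[day], tmax=tmax_a[day], rad=rad_a[day], rain=rain_a[day]
        )

        # today's soil EC as seen by the crop
        if mode == "measured":
            ec = float(daily_ec[day])
        else:
            ec = soil_mod.root_zone_ec(profile, state.root_depth_mm, constants)

        # irrigation: scheduled events, or top the pond up with fresh water
        if schedule is not None:
            irr_depth = 0.0
            salt_in = 0.0
            irr_ec = 0.0
            for ev in events_by_day.get(day, ()):
                applied = ev
                if max_ec_manager is not None and ec >= max_ec_manager:
                    applied = IrrigationEvent(ev.day, ev.depth_mm, manager_fresh_ec)
                irr_depth += applied.depth_mm
                salt_in += irrigation_salt_load(applied, constants)
                irr_ec = applied.ec_dsm
        else:
            irr_depth = max(0.0, auto_flood_depth_mm - pond.depth_mm)
            salt_in = 0.0
            irr_ec = 0.0

        fs_tr = salinity_params.fs_tr(ec, normalize=normalize_fs)
        fs_pn = salinity_params.fs_pn(ec, normalize=normalize_fs)

        ponded = pond.depth_mm > 0
        frac = soil_mod._root_fractions(profile, min(state.root_depth_mm, profile.depth_mm))
        weights = np.array([l.thickness_mm for l in profile.layers]) * frac
        taus = np.array(
            [soil_mod.matric_tension(l, ponded=ponded) for l in profile.layers]
        )
        matric = float((weights * taus).sum() / weights.sum())
        tension = matric + osmotic_tension(ec, constants)
        drought = drought_factor(tension, crop_params)

        fint = 1.0 - math.exp(-crop_params.k_ext * state.lai)
        et0 = reference_et(wx)
        t_pot = et0 * fint
        e_pot = et0 - t_pot
        demand = t_pot * drought * fs_tr

        fluxes = soil_mod.step_water(
            profile,
            pond,
            rain_mm=wx.rain,
            irrigation_mm=irr_depth,
            pot_evap_mm=e_pot,
            transp_demand_mm=demand,
            root_depth_mm=state.root_depth_mm,
        )
        soil_mod.step_salt(profile, pond, salt_in, fluxes, constants)

        growth = daily_growth(
            state,
            wx,
            fs_pn=fs_pn,
            fs_tr=fs_tr,
            drought=drought,
            params=crop_params,
            water_supply_mm=fluxes.transpiration,
        )

        rows.append(
            dict(
                day=day,
                dvs=state.dvs,
                lai=state.lai,
                wagt=state.wagt,
                wso=state.wso,
                ec=ec,
                fs_pn=fs_pn,
                fs_tr=fs_tr,
                drought=drought,
                t_pot=growth.t_pot_mm,
                t_act=growth.t_act_mm,
                growth=growth.growth_kg_ha,
                irr_depth=irr_depth,
                irr_ec=irr_ec,
                pond_depth=pond.depth_mm,
            )
        )

        tt = thermal_time(wx.tmin, wx.tmax, crop_params.tbase)
        state.dvs = advance_dvs(state.dvs, tt, crop_params)
        state.root_depth_mm = min(
            crop_params.root_depth_max_mm,
            state.root_depth_mm + crop_params.root_growth_mm_d,
        )

        if state.dvs >= 2.0:
            maturity_day = day
            break

    if maturity_day is None:
        raise IncompleteSeasonError(
            f"weather table ({n_days} days) ended before maturity (DVS "
            f"{state.dvs:.2f})"
        )

    daily = pd.DataFrame(rows)
    return SeasonResult(
        daily=daily,
        yield_kg_ha=state.wso,
        total_transpiration_mm=state.cum_transpiration_mm,
        maturity_day=maturity_day,
        genotype=salinity_params.genotype,
    )
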