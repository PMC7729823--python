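"""Phenology, canopy growth and the full season loop."""

import math

import numpy as np
import pytest

from paddysalt.crop import (
    CropError,
    CropParams,
    CropState,
    DailyWeather,
    IncompleteSeasonError,
    advance_dvs,
    daily_growth,
    drought_factor,
    partition_fractions,
    reference_et,
    simulate_season,
    thermal_time,
)
from paddysalt.salinity import ECMeasurementSeries
from paddysalt.soil import default_pond, default_profile
from paddysalt.synth import generate_irrigation_schedule


class TestThermalTime:
    @pytest.mark.parametrize(
        "tmin, tmax, tbase, expected",
        [(22, 30, 8, 18.0), (5, 7, 8, 0.0), (8, 8, 8, 0.0)],
    )
    def test_values(self, tmin, tmax, tbase, expected):
        assert thermal_time(tmin, tmax, tbase) == pytest.approx(expected)

    def test_inverted_range_rejected(self):
        with pytest.raises(CropError):
            thermal_time(20, 10, 8)


class TestAdvanceDvs:
    def test_vegetative_step(self, crop_params):
        p = crop_params.replace(dvr_veg=0.0009)
        assert advance_dvs(0.5, 20.0, p) == pytest.approx(0.518)

    def test_zero_thermal_time_is_identity(self, crop_params):
        assert advance_dvs(0.7, 0.0, crop_params) == 0.7

    def test_crossing_flowering_splits_the_day(self):
        p = CropParams(dvr_veg=0.001, dvr_rep=0.002)
        # 0.95 -> flowering after 50 degC-day, remaining 50 at the rep rate
        assert advance_dvs(0.95, 100.0, p) == pytest.approx(1.0 + 0.002 * 50)

    def test_capped_at_maturity(self, crop_params):
        assert advance_dvs(1.99, 1e5, crop_params) == 2.0


class TestReferenceET:
    def test_zero_radiation_is_zero(self):
        assert reference_et(DailyWeather(22, 30, 0.0, 0.0)) == 0.0

    def test_tropical_day_in_plausible_band(self):
        et = reference_et(DailyWeather(24, 30, 20.0, 0.0))
        assert 4.0 <= et <= 7.0

    def test_linear_in_radiation(self):
        et1 = reference_et(DailyWeather(24, 30, 10.0, 0.0))
        et2 = reference_et(DailyWeather(24, 30, 20.0, 0.0))
        assert et2 == pytest.approx(2 * et1)


class TestDroughtFactor:
    @pytest.mark.parametrize(
        "tau, expected", [(0.0, 1.0), (1500.0, 0.0), (765.0, 0.5), (30.0, 1.0)]
    )
    def test_piecewise_linear(self, tau, expected, crop_params):
        assert drought_factor(tau, crop_params) == pytest.approx(expected)

    def test_clamped_beyond_max(self, crop_params):
        assert drought_factor(1e6, crop_params) == 0.0


class TestPartitioning:
    def test_fractions_sum_to_one_across_dvs(self):
        for dvs in np.linspace(0, 2, 41):
            assert sum(partition_fractions(dvs)) == pytest.approx(1.0, abs=1e-12)

    def test_panicle_only_after_grain_filling(self):
        leaf, stem, pan = partition_fractions(1.5)
        assert (leaf, stem, pan) == (0.0, 0.0, 1.0)


class TestDailyGrowth:
    def _state(self, lai, params):
        state = CropState.at_transplanting(params)
        state.leaf_green_kg_ha = lai / params.sla
        state.lai = lai
        return state

    def test_no_canopy_no_growth(self, crop_params):
        state = self._state(0.0, crop_params)
        state.leaf_green_kg_ha = 0.0
        res = daily_growth(
            state, DailyWeather(24, 30, 18.0, 0.0), 1.0, 1.0, 1.0, crop_params
        )
        assert res.growth_kg_ha == 0.0
        assert res.t_act_mm == 0.0
        assert res.pcew == 1.0  # convention when potential transpiration is 0

    def test_toy_day_matches_hand_arithmetic(self):
        # LAI 3, Rs 18, k 0.6, RUE 2.2, all factors 1:
        # growth = 2.2 * 9 * (1 - e^-1.8) * 10 = 165.1 kg/ha
        params = CropParams(rue=2.2, k_ext=0.6)
        state = self._state(3.0, params)
        res = daily_growth(
            state, DailyWeather(24, 30, 18.0, 0.0), 1.0, 1.0, 1.0, params
        )
        expected = 2.2 * 9 * (1 - math.exp(-1.8)) * 10
        assert res.growth_kg_ha == pytest.approx(expected, abs=0.05)

    def test_supply_cap_limits_transpiration_and_growth(self, crop_params):
        state1 = self._state(3.0, crop_params)
        free = daily_growth(
            state1, DailyWeather(24, 30, 18.0, 0.0), 1.0, 1.0, 1.0, crop_params
        )
        state2 = self._state(3.0, crop_params)
        capped = daily_growth(
            state2,
            DailyWeather(24, 30, 18.0, 0.0),
            1.0,
            1.0,
            1.0,
            crop_params,
            water_supply_mm=free.t_act_mm / 2,
        )
        assert capped.t_act_mm == pytest.approx(free.t_act_mm / 2)
        assert capped.pcew == pytest.approx(0.5)
        assert capped.growth_kg_ha == pytest.approx(free.growth_kg_ha / 2)


class TestSimulateSeason:
    def _run(self, weather, ec, **kwargs):
        return simulate_season(
            weather,
            default_profile(),
            default_pond(),
            CropParams(),
            kwargs.pop("params"),
            mode="measured",
            ec_series=ECMeasurementSeries((0,), (ec,)),
            **kwargs,
        )

    def test_deterministic(self, season_weather, ir64):
        r1 = self._run(season_weather, 4.0, params=ir64)
        r2 = self._run(season_weather, 4.0, params=ir64)
        assert r1.yield_kg_ha == r2.yield_kg_ha
        assert r1.daily.equals(r2.daily)

    def test_yield_monotone_in_salinity(self, season_weather, ir64):
        yields = [
            self._run(season_weather, ec, params=ir64).yield_kg_ha
            for ec in (0.0, 4.0, 8.0, 12.0)
        ]
        assert all(a > b for a, b in zip(yields, yields[1:]))

    def test_yield_monotone_in_tolerance_parameters(self, season_weather, ir64):
        for name in ("b_tr", "b_pn"):
            yields = [
                self._run(
                    season_weather, 8.0, params=ir64.replace(**{name: b})
                ).yield_kg_ha
                for b in (6.0, 8.0, 10.0, 14.0)
            ]
            assert all(b >= a for a, b in zip(yields, yields[1:])), name

    def test_pool_invariants_hold_daily(self, season_weather, ir64):
        r = self._run(season_weather, 6.0, params=ir64)
        d = r.daily
        assert (d["wso"] <= d["wagt"] + 1e-9).all()
        assert (d[["wagt", "wso", "lai"]] >= 0).all().all()
        assert r.total_transpiration_mm == pytest.approx(d["t_act"].sum())
        assert r.yield_kg_ha == pytest.approx(d["wso"].iloc[-1])

    def test_fresh_water_biomass_in_plausible_band(self, season_weather, ir64):
        # guards gross unit errors in the default parameterization
        r = self._run(season_weather, 0.0, params=ir64)
        assert 8000 <= r.final_wagt <= 20000

    def test_unstressed_limit_reaches_potential(self, season_weather, ir64):
        # normalized stress factors, fresh water, ponded soil: all factors 1
        r = self._run(season_weather, 0.0, params=ir64, normalize_fs=True)
        d = r.daily
        assert d["fs_pn"].to_numpy() == pytest.approx(1.0, abs=1e-12)
        assert d["fs_tr"].to_numpy() == pytest.approx(1.0, abs=1e-12)
        assert (d["drought"] == 1.0).all()
        # transpiration met in full whenever there is canopy demand
        assert d["t_act"].to_numpy() == pytest.approx(
            (d["t_pot"] * d["fs_tr"] * d["drought"]).to_numpy(), abs=1e-9
        )

    def test_short_weather_is_explicit_error(self, season_weather, ir64):
        with pytest.raises(IncompleteSeasonError):
            self._run(season_weather.iloc[:40], 0.0, params=ir64)

    def test_cross_mode_consistency(self, season_weather, ir64):
        # a simulated-EC season replayed through measured-EC mode with its
        # own realized daily EC series reproduces the yield
        sched = generate_irrigation_schedule(6.0, interval_d=2, depth_mm=30,
                                             season_length_d=150)
        sim = simulate_season(
            season_weather, default_profile(), default_pond(), CropParams(),
            ir64, mode="simulated", schedule=sched,
        )
        series = ECMeasurementSeries(tuple(sim.daily["day"]), tuple(sim.daily["ec"]))
        replay = simulate_season(
            season_weather, default_profile(), default_pond(), CropParams(),
            ir64, mode="measured", ec_series=series, schedule=sched,
        )
        assert replay.yield_kg_ha == pytest.approx(sim.yield_kg_ha, rel=0.02)

    def test_ponded_season_stress_is_osmotic_only(self, season_weather, ir64):
        # under continuous flooding matric tension is ~0, so the drought
        # factor is governed by the osmotic term alone
        r = self._run(season_weather, 4.0, params=ir64)
        assert (r.daily["pond_depth"] > 0).all()
        expected = (1500.0 - 40.55 * 4.0) / (1500.0 - 30.0)
        assert r.daily["drought"].to_numpy() == pytest.approx(
            np.full(len(r.daily), expected), abs=1e-9
        )

    def test_salinity_manager_suspends_salt(self, season_weather, ir64):
        sched = generate_irrigation_schedule(12.0, interval_d=2, depth_mm=30,
                                             season_length_d=150)
        r = simulate_season(
            season_weather, default_profile(), default_pond(), CropParams(),
            ir64, mode="simulated", schedule=sched, max_ec_manager=8.0,
            manager_fresh_ec=1.0,
        )
        irr_days = r.daily[r.daily["irr_depth"] > 0]
        suspended = irr_days[irr_days["irr_ec"] == 1.0]
        assert len(suspended) > 0
        assert (irr_days.loc[irr_days["ec"] >= 8.0, "irr_ec"] == 1.0).all()
        assert r.daily["ec"].max() < 14.0
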