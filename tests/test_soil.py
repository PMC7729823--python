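"""Water and chloride balance of the ponded tipping-bucket profile."""

import numpy as np
import pytest

from paddysalt.soil import (
    IrrigationEvent,
    Pond,
    SoilError,
    SoilLayer,
    SoilProfile,
    default_pond,
    default_profile,
    irrigation_salt_load,
    matric_tension,
    root_zone_ec,
    step_salt,
    step_water,
)


def run_day(profile, pond, rain=0.0, irr=0.0, ec_iw=0.0, evap=0.0, transp=0.0,
            root_depth=None):
    """One coupled water+salt day; returns (water fluxes, salt fluxes)."""
    ev = IrrigationEvent(0, irr, ec_iw)
    wf = step_water(profile, pond, rain, irr, evap, transp, root_depth)
    sf = step_salt(profile, pond, irrigation_salt_load(ev), wf)
    return wf, sf


class TestIrrigationSaltLoad:
    @pytest.mark.parametrize(
        "depth, ec, expected",
        [(100.0, 1.0, 640.0), (30.0, 0.0, 0.0), (50.0, 4.0, 1280.0)],
    )
    def test_load(self, depth, ec, expected):
        assert irrigation_salt_load(IrrigationEvent(0, depth, ec)) == pytest.approx(
            expected
        )


class TestStepWater:
    def test_no_flux_profile_at_fc_is_fixed_point(self):
        profile = default_profile()
        pond = Pond(depth_mm=0.0)
        before = [l.water_mm for l in profile.layers]
        fluxes = step_water(profile, pond, 0, 0, 0, 0)
        assert [l.water_mm for l in profile.layers] == pytest.approx(before)
        assert fluxes.runoff == fluxes.drainage == fluxes.transpiration == 0

    def test_rain_above_bund_runs_off(self):
        profile = default_profile()
        pond = default_pond(depth_mm=95.0, bund_height_mm=100.0, percolation_mm_d=0.0)
        fluxes = step_water(profile, pond, rain_mm=20.0, irrigation_mm=0.0,
                            pot_evap_mm=0.0, transp_demand_mm=0.0)
        assert fluxes.runoff == pytest.approx(15.0)
        assert pond.depth_mm == pytest.approx(100.0)

    def test_transpiration_capped_by_extractable_water(self):
        profile = default_profile(theta_init=0.16)  # barely above wilting
        pond = Pond(depth_mm=0.0)
        extractable = sum(
            (l.theta - l.theta_wp) * l.thickness_mm for l in profile.layers
        )
        fluxes = step_water(profile, pond, 0, 0, 0, transp_demand_mm=50.0)
        assert fluxes.transpiration == pytest.approx(extractable)
        for l in profile.layers:
            assert l.water_mm >= 0

    def test_cascade_spills_above_field_capacity(self):
        profile = default_profile()
        pond = default_pond(depth_mm=50.0, percolation_mm_d=8.0)
        fluxes = step_water(profile, pond, 0, 0, 0, 0)
        assert fluxes.percolation == pytest.approx(8.0)
        # profile started at field capacity, so everything percolated drains
        assert fluxes.drainage == pytest.approx(8.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(SoilError):
            step_water(default_profile(), default_pond(), -1.0, 0, 0, 0)

    def test_empty_profile_rejected(self):
        with pytest.raises(SoilError):
            SoilProfile([])


class TestStepSalt:
    def test_no_flux_no_change(self):
        profile = default_profile(chloride_kg_ha=100.0)
        pond = Pond(depth_mm=0.0)
        wf = step_water(profile, pond, 0, 0, 0, 0)
        sf = step_salt(profile, pond, 0.0, wf)
        assert profile.total_chloride_kg_ha == pytest.approx(100.0)
        assert sf.leached == sf.plant_uptake == sf.runoff == 0

    def test_percolation_moves_proportional_mass(self):
        profile = default_profile()
        pond = Pond(depth_mm=100.0, chloride_kg_ha=640.0, percolation_mm_d=10.0)
        wf = step_water(profile, pond, 0, 0, 0, 0)
        assert wf.percolation == pytest.approx(10.0)
        step_salt(profile, pond, 0.0, wf)
        # 10% of the pond water moved, carrying 10% of its chloride
        assert pond.chloride_kg_ha == pytest.approx(640.0 * 0.9)

    def test_fresh_water_keeps_clean_profile_clean(self):
        profile = default_profile()
        pond = default_pond()
        for _ in range(60):
            run_day(profile, pond, irr=10.0, ec_iw=0.0, evap=3.0, transp=2.0)
        assert root_zone_ec(profile, 400.0) == pytest.approx(0.0)

    def test_saline_irrigation_accumulates_monotonically(self):
        profile = default_profile(n_layers=6, thickness_mm=300.0)
        pond = default_pond(percolation_mm_d=2.0)
        totals = []
        for _ in range(40):
            run_day(profile, pond, irr=6.0, ec_iw=6.0, evap=2.0, transp=1.0)
            totals.append(pond.chloride_kg_ha + profile.total_chloride_kg_ha)
        assert all(b >= a for a, b in zip(totals, totals[1:]))
        assert totals[-1] > 0

    def test_ledger_closes_over_random_schedule(self):
        rng = np.random.default_rng(7)
        profile = default_profile()
        pond = default_pond()
        total_in = total_out = 0.0
        start = pond.chloride_kg_ha + profile.total_chloride_kg_ha
        for _ in range(120):
            irr = float(rng.uniform(0, 30))
            ec = float(rng.uniform(0, 8))
            wf, sf = run_day(
                profile,
                pond,
                rain=float(rng.uniform(0, 25)),
                irr=irr,
                ec_iw=ec,
                evap=float(rng.uniform(0, 6)),
                transp=float(rng.uniform(0, 6)),
            )
            total_in += sf.applied
            total_out += sf.leached + sf.plant_uptake + sf.runoff
        end = pond.chloride_kg_ha + profile.total_chloride_kg_ha
        assert end - start == pytest.approx(total_in - total_out, abs=1e-6)

    def test_flushing_converges_to_irrigation_ec(self):
        # the Eq-consistency loop: steady saline flushing with no evaporative
        # concentration pulls the root-zone solution to the irrigation EC
        profile = default_profile()
        pond = default_pond(depth_mm=50.0)
        for _ in range(300):
            run_day(profile, pond, irr=10.0, ec_iw=4.0)
        assert root_zone_ec(profile, profile.depth_mm) == pytest.approx(4.0, rel=1e-4)


class TestMatricTension:
    def test_saturated_or_ponded_is_zero(self):
        layer = SoilLayer(200, 0.5, 0.35, 0.15, theta=0.5)
        assert matric_tension(layer) == 0.0
        drier = SoilLayer(200, 0.5, 0.35, 0.15, theta=0.3)
        assert matric_tension(drier, ponded=True) == 0.0

    def test_halving_theta_scales_by_two_to_shape(self):
        l1 = SoilLayer(200, 0.5, 0.35, 0.15, theta=0.4, shape=5.0)
        l2 = SoilLayer(200, 0.5, 0.35, 0.15, theta=0.2, shape=5.0)
        assert matric_tension(l2) / matric_tension(l1) == pytest.approx(2.0**5)

    def test_monotone_decreasing_in_theta(self):
        thetas = np.linspace(0.05, 0.49, 30)
        taus = [
            matric_tension(SoilLayer(200, 0.5, 0.35, 0.15, theta=t)) for t in thetas
        ]
        assert all(b < a for a, b in zip(taus, taus[1:]))

    def test_dry_layer_rejected(self):
        layer = SoilLayer(200, 0.5, 0.35, 0.15, theta=0.3)
        layer.theta = 0.0
        with pytest.raises(SoilError):
            matric_tension(layer)


class TestRootZoneEC:
    def _profile_with_conc(self, ppm_per_layer):
        layers = []
        for ppm in ppm_per_layer:
            l = SoilLayer(200, 0.5, 0.35, 0.15, theta=0.35)
            l.chloride_kg_ha = ppm * l.water_mm / 100.0
            layers.append(l)
        return SoilProfile(layers)

    def test_uniform_640ppm_is_one_dsm(self):
        profile = self._profile_with_conc([640.0] * 4)
        assert root_zone_ec(profile, 800.0) == pytest.approx(1.0)

    def test_zero_chloride_is_zero(self):
        assert root_zone_ec(default_profile(), 400.0) == 0.0

    def test_two_layer_weighted_mean(self):
        profile = self._profile_with_conc([640.0, 1920.0])
        assert root_zone_ec(profile, 400.0) == pytest.approx(2.0)

    def test_partial_layer_weighting(self):
        profile = self._profile_with_conc([640.0, 1920.0])
        # roots cover layer 1 fully, layer 2 half: (640*200 + 1920*100)/300
        expected = (640 * 200 + 1920 * 100) / 300 / 640
        assert root_zone_ec(profile, 300.0) == pytest.approx(expected)

    def test_overdeep_roots_clamped_with_warning(self, caplog):
        profile = self._profile_with_conc([640.0] * 4)
        with caplog.at_level("WARNING"):
            ec = root_zone_ec(profile, 5000.0)
        assert ec == pytest.approx(1.0)
        assert any("clamping" in r.message for r in caplog.records)


class TestInvariantGuards:
    def test_layer_ordering_invariant(self):
        with pytest.raises(SoilError):
            SoilLayer(200, theta_sat=0.3, theta_fc=0.35, theta_wp=0.15, theta=0.2)

    def test_pond_invariants(self):
        with pytest.raises(SoilError):
            Pond(depth_mm=-1.0)
        with pytest.raises(SoilError):
            IrrigationEvent(0, -5.0, 1.0)
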