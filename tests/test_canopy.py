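import dataclasses
import datetime as dt

import numpy as np
import pytest

import lentilsim as ls
from lentilsim.canopy import (daily_biomass, light_interception,
                              row_spacing_modifier, simulate_season,
                              update_harvest_index, update_leaf_area,
                              water_demand, water_stress)
from lentilsim.phenology import Stage


class TestLeafArea:
    def test_no_new_nodes_no_lai(self, jumbo):
        assert update_leaf_area(5.0, 5.0, jumbo, 120.0) == 0.0

    def test_single_node_constant_size(self, jumbo):
        # below the first anchor the leaf size is flat at the node-8 value
        cv = dataclasses.replace(jumbo, leaf_size_node8=200.0,
                                 leaf_size_node14=200.0)
        dlai = update_leaf_area(3.0, 4.0, cv, 120.0, leaves_per_node=1.0)
        assert dlai == pytest.approx(200.0 * 120.0 * 1e-6)  # 0.024

    def test_linear_in_leaf_size(self, jumbo):
        cv2 = dataclasses.replace(jumbo,
                                  leaf_size_node8=2 * jumbo.leaf_size_node8,
                                  leaf_size_node14=2 * jumbo.leaf_size_node14)
        a = update_leaf_area(8.0, 10.5, jumbo, 120.0)
        b = update_leaf_area(8.0, 10.5, cv2, 120.0)
        assert b == pytest.approx(2 * a)

    def test_rejects_node_regression(self, jumbo):
        with pytest.raises(ValueError):
            update_leaf_area(5.0, 4.0, jumbo, 120.0)


class TestLightInterception:
    def test_bare_ground(self):
        assert light_interception(0.0, 0.5) == 0.0

    def test_closed_form(self):
        assert light_interception(2.0, 0.5) == pytest.approx(1 - np.exp(-1),
                                                             abs=1e-12)

    def test_monotone_in_lai(self):
        vals = [light_interception(l, 0.5) for l in np.linspace(0, 6, 30)]
        assert all(b > a for a, b in zip(vals[:-1], vals[1:]))
        assert vals[-1] < 1.0


class TestRowSpacing:
    @pytest.mark.parametrize("spacing,mult", [(190.0, 1.0), (380.0, 0.85),
                                              (285.0, 0.925), (100.0, 1.0),
                                              (500.0, 0.85)])
    def test_modifier(self, spacing, mult):
        assert row_spacing_modifier(spacing) == pytest.approx(mult)


class TestBiomassAndHI:
    def test_daily_biomass_product(self):
        assert daily_biomass(20.0, 0.5, 1.2, 1.0) == pytest.approx(12.0)
        assert daily_biomass(20.0, 0.5, 1.2, 0.0) == 0.0
        assert daily_biomass(20.0, 0.0, 1.2, 1.0) == 0.0

    def test_hi_linear_rise_during_grain_fill(self):
        hi = 0.0
        for _ in range(10):
            hi, _ = update_harvest_index(hi, 400.0, Stage.START_GRAIN_FILL,
                                         0.0139, 0.6)
        assert hi == pytest.approx(0.139)

    def test_hi_capped_at_max(self):
        hi, _ = update_harvest_index(0.6, 400.0, Stage.START_GRAIN_FILL,
                                     0.0139, 0.6)
        assert hi == 0.6

    def test_yield_is_hi_times_biomass(self):
        _, y = update_harvest_index(0.10, 400.0, Stage.FLOWERING, 0.01, 0.6)
        assert y == pytest.approx(40.0)

    def test_hi_unchanged_outside_window(self):
        hi, _ = update_harvest_index(0.2, 400.0, Stage.FLOWERING, 0.01, 0.6)
        assert hi == 0.2


class TestWaterDemandStress:
    def test_demand_arithmetic(self):
        assert water_demand(10.0, 2.0, 0.005) == pytest.approx(4.0)
        assert water_demand(0.0, 2.0) == 0.0

    def test_demand_linear_in_vpd(self):
        assert water_demand(10.0, 4.0, 0.005) == pytest.approx(
            2 * water_demand(10.0, 2.0, 0.005))

    def test_stress_ratio(self):
        assert water_stress(5.0, 4.0) == 1.0
        assert water_stress(2.0, 4.0) == 0.5
        assert water_stress(0.0, 4.0) == 0.0
        assert water_stress(0.0, 0.0) == 1.0


class TestSimulateSeason:
    def test_unlimited_water_closed_form(self, medium_weather, soil, jumbo,
                                         mgmt):
        """With the profile refilled daily, biomass equals RUE x cumulative
        intercepted radiation exactly."""
        res = simulate_season(medium_weather, soil, jumbo, mgmt,
                              well_watered=True)
        assert not res.failed
        assert res.summary["final_biomass_g_m2"] == pytest.approx(
            jumbo.rue * res.summary["cum_ipar_mj_m2"], rel=1e-6)

    def test_deterministic(self, medium_weather, soil, jumbo, mgmt):
        r1 = simulate_season(medium_weather, soil, jumbo, mgmt)
        r2 = simulate_season(medium_weather, soil, jumbo, mgmt)
        assert r1.daily.equals(r2.daily)
        assert r1.summary["final_yield_t_ha"] == r2.summary["final_yield_t_ha"]

    def test_yield_summary_consistent_with_daily(self, medium_weather, soil,
                                                 jumbo, mgmt):
        res = simulate_season(medium_weather, soil, jumbo, mgmt)
        last = res.daily.iloc[-1]
        assert res.summary["final_yield_g_m2"] == pytest.approx(last["yield"])
        assert res.summary["final_yield_t_ha"] == pytest.approx(
            last["yield"] * 0.01)

    def test_yield_bounded_by_hi_max_and_biomass_monotone(
            self, medium_weather, soil, jumbo, mgmt):
        res = simulate_season(medium_weather, soil, jumbo, mgmt)
        d = res.daily
        assert (d["yield"] <= jumbo.hi_max * d.biomass + 1e-9).all()
        assert (np.diff(d.biomass) >= -1e-9).all()
        assert (np.diff(d.lai) >= -1e-9).all()

    @pytest.mark.parametrize("field,factor", [("rue", 1.1),
                                              ("hi_rate", 1.1)])
    def test_yield_monotone_in_traits_unstressed(self, medium_weather, soil,
                                                 jumbo, mgmt, field, factor):
        base = simulate_season(medium_weather, soil, jumbo, mgmt,
                               well_watered=True)
        boosted = dataclasses.replace(jumbo,
                                      **{field: getattr(jumbo, field) * factor})
        res = simulate_season(medium_weather, soil, boosted, mgmt,
                              well_watered=True)
        assert (res.summary["final_yield_t_ha"]
                > base.summary["final_yield_t_ha"])

    def test_yield_monotone_in_leaf_size_unstressed(self, medium_weather,
                                                    soil, jumbo, mgmt):
        base = simulate_season(medium_weather, soil, jumbo, mgmt,
                               well_watered=True)
        big = dataclasses.replace(
            jumbo, leaf_size_node8=jumbo.leaf_size_node8 * 1.2,
            leaf_size_node14=jumbo.leaf_size_node14 * 1.2)
        res = simulate_season(medium_weather, soil, big, mgmt,
                              well_watered=True)
        assert (res.summary["final_yield_t_ha"]
                >= base.summary["final_yield_t_ha"])

    def test_trait_monotonicity_over_random_baselines(self, medium_weather,
                                                      soil, mgmt):
        rng = np.random.default_rng(3)
        base = ls.get_cultivar("PBA Hallmark XT")
        for _ in range(3):
            cv = dataclasses.replace(
                base,
                rue=rng.uniform(0.9, 1.3),
                hi_rate=rng.uniform(0.009, 0.0125),
                leaf_size_node8=rng.uniform(150, 230),
                node_app_rate=rng.uniform(57, 61))
            y0 = simulate_season(medium_weather, soil, cv, mgmt,
                                 well_watered=True).summary["final_yield_t_ha"]
            up = dataclasses.replace(cv, rue=cv.rue * 1.15)
            y1 = simulate_season(medium_weather, soil, up, mgmt,
                                 well_watered=True).summary["final_yield_t_ha"]
            assert y1 >= y0

    def test_residue_rarely_hurts_yield(self, soil):
        """6 t/ha of stubble should not reduce yield in at least 95% of
        random water-limited seasons (it conserves soil water)."""
        dry_soil = ls.generate_soil(110.0, 7, seed=30)
        wins = 0
        n = 20
        for seed in range(n):
            w = ls.generate_weather(ls.CLIMATE_CLASSES["low"], 1,
                                    seed=500 + seed)
            y = {}
            for resid in (0.0, 6.0):
                m = ls.ManagementConfig(sowing_date=dt.date(2000, 5, 12),
                                        initial_residue=resid)
                y[resid] = simulate_season(
                    w, dry_soil, ls.get_cultivar("PBA Hallmark XT"),
                    m).summary["final_yield_t_ha"]
            if y[6.0] >= y[0.0] - 1e-9:
                wins += 1
        assert wins / n >= 0.95

    def test_failure_flagged_when_weather_ends(self, soil, jumbo):
        short = ls.generate_weather(ls.CLIMATE_CLASSES["medium"], 1, seed=7)
        short = short.window(dt.date(2000, 5, 12), dt.date(2000, 7, 1))
        mgmt = ls.ManagementConfig(sowing_date=dt.date(2000, 5, 12))
        res = simulate_season(short, soil, jumbo, mgmt)
        assert res.failed
        assert res.stage_reached != "maturity"

    def test_missing_sowing_window_raises(self, medium_weather, soil, jumbo):
        mgmt = ls.ManagementConfig(sowing_date=dt.date(2050, 5, 12))
        with pytest.raises(ValueError):
            simulate_season(medium_weather, soil, jumbo, mgmt)
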