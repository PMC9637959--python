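import datetime as dt
import itertools

import numpy as np
import pandas as pd
import pytest

import lentilsim as ls
from lentilsim.canopy import SimulationResult
from lentilsim.scenario import (Ideotype, apply_ideotype, build_ideotypes,
                                classify_environments, design_cells,
                                drought_impact, main_effect, run_factorial,
                                sensitivity_indices, total_effect)


class TestIdeotypes:
    def test_two_baselines_four_levels_gives_eight(self):
        bases = [ls.get_cultivar("PBA Jumbo2"),
                 ls.get_cultivar("PBA Hallmark XT")]
        assert len(build_ideotypes(bases)) == 8

    def test_joint_multiplier_scales_all_three_traits(self, jumbo):
        ide = Ideotype("x", jumbo.name,
                       {"leaf_size": 1.2, "rue": 1.2, "hi_rate": 1.2})
        derived = apply_ideotype(jumbo, ide)
        assert derived.rue == pytest.approx(jumbo.rue * 1.2)
        assert derived.hi_rate == pytest.approx(jumbo.hi_rate * 1.2)
        assert derived.leaf_size_node8 == pytest.approx(
            jumbo.leaf_size_node8 * 1.2)
        # phenology untouched
        assert derived.tt_emerg_to_endjuv == jumbo.tt_emerg_to_endjuv
        assert derived.node_app_rate == jumbo.node_app_rate

    def test_unit_multiplier_is_identity(self, jumbo):
        _, derived = build_ideotypes([jumbo], levels=(1.0,))[0]
        for f in ("rue", "hi_rate", "leaf_size_node8", "leaf_size_node14"):
            assert getattr(derived, f) == getattr(jumbo, f)

    def test_per_trait_mode_counts(self, jumbo):
        out = build_ideotypes([jumbo], levels=(1.1, 1.2), joint=False)
        assert len(out) == 2 * 3  # levels x traits

    def test_rejects_nonpositive_multiplier(self, jumbo):
        with pytest.raises(ValueError):
            build_ideotypes([jumbo], levels=(0.0,))


def _stub_engine(fail_for=None):
    """Fast deterministic stand-in engine for factorial accounting tests."""
    def engine(weather, soil, cultivar, mgmt, **kw):
        failed = fail_for is not None and fail_for(mgmt)
        yield_ = (mgmt.sowing_date.month + mgmt.initial_residue
                  + mgmt.row_spacing / 1000 + len(cultivar.name) * 0.01)
        summary = {
            "final_yield_t_ha": yield_,
            "maturity_date": pd.Timestamp(mgmt.sowing_date)
            + pd.Timedelta(days=120),
            "paw_at_sowing_mm": 50.0,
            "in_season_rain_mm": 100.0,
        }
        return SimulationResult(daily=pd.DataFrame(), summary=summary,
                                failed=failed,
                                stage_reached="flowering" if failed
                                else "maturity")
    return engine


@pytest.fixture(scope="module")
def two_site_weather():
    sites = []
    for i in range(2):
        w = ls.generate_weather(ls.CLIMATE_CLASSES["medium"], 3, seed=70 + i,
                                site_id=f"site{i}")
        sites.append({"site": f"site{i}", "weather": w,
                      "soil": ls.generate_soil(120.0, 5, seed=i)})
    return sites


class TestFactorial:
    def test_row_count_product_rule(self, two_site_weather, jumbo):
        genotypes = {"a": jumbo, "b": jumbo}
        table = run_factorial(two_site_weather, genotypes=genotypes,
                              engine=_stub_engine())
        # 2 sites x 3 years x 5 TOS x 2 stubble x 2 spacing x 2 genotypes
        assert len(table) == 2 * 3 * 5 * 2 * 2 * 2

    def test_single_cell_single_row(self, two_site_weather, jumbo):
        table = run_factorial(two_site_weather[:1], tos_dates=((5, 12),),
                              stubble_levels=(0.0,), spacings=(190.0,),
                              genotypes={"a": jumbo}, engine=_stub_engine())
        assert len(table) == 3  # one row per year of the 3-year series

    def test_environment_cell_count(self, two_site_weather, jumbo):
        table = run_factorial(two_site_weather, genotypes={"a": jumbo},
                              engine=_stub_engine())
        cells = table.groupby(["site", "year"]).ngroups
        assert cells == design_cells(2, 3)

    def test_failed_seasons_flagged_not_dropped(self, two_site_weather,
                                                jumbo):
        fail_june = _stub_engine(fail_for=lambda m: m.sowing_date.month == 6)
        table = run_factorial(two_site_weather[:1], genotypes={"a": jumbo},
                              engine=fail_june)
        assert table.failed.sum() == 3 * 2 * 2 * 2  # June TOS rows
        assert table.loc[table.failed, "yield_t_ha"].isna().all()

    def test_empty_factor_rejected(self, two_site_weather, jumbo):
        with pytest.raises(ValueError):
            run_factorial(two_site_weather, tos_dates=(),
                          genotypes={"a": jumbo})
        with pytest.raises(ValueError):
            run_factorial(two_site_weather, genotypes={})


class TestEnvironmentClassification:
    def _table(self, gsrs):
        rows = []
        for i, g in enumerate(gsrs):
            rows.append({"site": f"s{i}", "year": 2000, "gsr_mm": g,
                         "yield_t_ha": 1.0})
        return pd.DataFrame(rows)

    def test_terciles_of_nine_cells(self):
        out = classify_environments(self._table(range(100, 1000, 100)))
        counts = out.rainfall_class.value_counts()
        assert counts["low"] == 3 and counts["medium"] == 3 \
            and counts["high"] == 3
        assert (out.sort_values("gsr_mm").rainfall_class.tolist()
                == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3)

    def test_degenerate_identical_gsr_rejected(self):
        with pytest.raises(ValueError):
            classify_environments(self._table([300] * 9))

    def test_row_order_invariance(self):
        t = self._table(range(100, 1000, 100))
        shuffled = t.sample(frac=1, random_state=4)
        a = classify_environments(t).set_index("site").rainfall_class
        b = classify_environments(shuffled).set_index("site").rainfall_class
        assert a.sort_index().equals(b.sort_index())


class TestDroughtImpact:
    def _table(self):
        rows = []
        for cls, y in (("high", 2.0), ("low", 1.0), ("medium", 2.2)):
            for rep in range(3):
                rows.append({"site": cls, "year": 2000 + rep, "decade": 2000,
                             "genotype": "g", "stubble": 0.0,
                             "row_spacing": 190.0, "rainfall_class": cls,
                             "yield_t_ha": y})
        return pd.DataFrame(rows)

    def test_loss_percentages_and_sign(self):
        out = drought_impact(self._table(), group_by=("rainfall_class",))
        loss = out.set_index("rainfall_class").loss_pct
        assert loss["high"] == pytest.approx(0.0)
        assert loss["low"] == pytest.approx(50.0)
        assert loss["medium"] == pytest.approx(-10.0)  # a gain

    def test_missing_high_class_rejected(self):
        t = self._table()
        t = t[t.rainfall_class != "high"]
        with pytest.raises(ValueError):
            drought_impact(t)

    def test_common_reference_filter(self):
        t = self._table()
        better = t.copy()
        better["genotype"] = "improved"
        better["yield_t_ha"] *= 1.5
        both = pd.concat([t, better], ignore_index=True)
        out = drought_impact(both, group_by=("rainfall_class", "genotype"),
                             reference_filter={"genotype": "g"})
        loss = out.set_index(["rainfall_class", "genotype"]).loss_pct
        assert loss[("low", "improved")] == pytest.approx(25.0)
        assert loss[("low", "g")] == pytest.approx(50.0)


def _brute_force_indices(table, factor, factors, response):
    """Nested-loop ME/TE oracle on a balanced factorial table."""
    y = table[response].to_numpy(float)
    var_y = np.var(y)
    levels = {f: sorted(table[f].unique()) for f in factors}
    cond = []
    for level in levels[factor]:
        cond.extend([table.loc[table[factor] == level, response].mean()]
                    * (table[factor] == level).sum())
    me = np.var(np.array(cond)) / var_y
    others = [f for f in factors if f != factor]
    means = np.empty(len(table))
    for combo in itertools.product(*(levels[f] for f in others)):
        mask = np.ones(len(table), bool)
        for f, v in zip(others, combo):
            mask &= (table[f] == v).to_numpy()
        if mask.any():
            means[mask] = y[mask].mean()
    te = 1 - np.var(means) / var_y
    return me, te


class TestSensitivityIndices:
    @pytest.fixture
    def additive_grid(self):
        rows = [{"x1": a, "x2": b, "y": a + b}
                for a in (-1, 1) for b in (-2, 2)]
        return pd.DataFrame(rows)

    @pytest.fixture
    def interaction_grid(self):
        rows = [{"x1": a, "x2": b, "y": a * b}
                for a in (-1, 1) for b in (-2, 2)]
        return pd.DataFrame(rows)

    def test_additive_grid_hand_values(self, additive_grid):
        assert main_effect(additive_grid, "x1", "y") == pytest.approx(0.2)
        assert main_effect(additive_grid, "x2", "y") == pytest.approx(0.8)
        assert total_effect(additive_grid, "x1", "y",
                            factors=["x1", "x2"]) == pytest.approx(0.2)
        assert total_effect(additive_grid, "x2", "y",
                            factors=["x1", "x2"]) == pytest.approx(0.8)

    def test_pure_interaction_grid(self, interaction_grid):
        assert main_effect(interaction_grid, "x1", "y") == pytest.approx(0.0)
        assert total_effect(interaction_grid, "x1", "y",
                            factors=["x1", "x2"]) == pytest.approx(1.0)

    def test_single_factor_main_effect_is_one(self):
        table = pd.DataFrame({"x1": [1, 2, 3], "y": [1.0, 3.0, 7.0]})
        assert main_effect(table, "x1", "y") == pytest.approx(1.0)

    def test_zero_variance_rejected(self, additive_grid):
        flat = additive_grid.assign(y=1.0)
        with pytest.raises(ValueError):
            main_effect(flat, "x1", "y")

    def test_matches_brute_force_on_random_balanced_factorials(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n_factors = rng.integers(2, 5)
            factors = [f"f{i}" for i in range(n_factors)]
            levels = [rng.integers(2, 5) for _ in factors]
            rows = [dict(zip(factors, combo))
                    for combo in itertools.product(
                        *(range(k) for k in levels))]
            table = pd.DataFrame(rows)
            table["y"] = rng.normal(size=len(table))
            for f in factors:
                me = main_effect(table, f, "y")
                te = total_effect(table, f, "y", factors=factors)
                bme, bte = _brute_force_indices(table, f, factors, "y")
                assert me == pytest.approx(bme, abs=1e-12)
                assert te == pytest.approx(bte, abs=1e-12)
                assert te >= me - 1e-9  # TE dominates ME on balanced grids

    def test_additive_response_main_effects_sum_to_one(self):
        rng = np.random.default_rng(21)
        factors = ["a", "b", "c"]
        effects = {f: rng.normal(size=3) for f in factors}
        rows = []
        for combo in itertools.product(range(3), repeat=3):
            rows.append(dict(zip(factors, combo),
                             y=sum(effects[f][i]
                                   for f, i in zip(factors, combo))))
        table = pd.DataFrame(rows)
        mes = [main_effect(table, f, "y") for f in factors]
        assert sum(mes) == pytest.approx(1.0, abs=1e-9)
        for f, me in zip(factors, mes):
            te = total_effect(table, f, "y", factors=factors)
            assert te == pytest.approx(me, abs=1e-9)

    def test_sensitivity_indices_table(self, additive_grid):
        out = sensitivity_indices(additive_grid, ["x1", "x2"], "y")
        assert set(out.factor) == {"x1", "x2"}
        assert out.main_effect.sum() == pytest.approx(1.0)
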