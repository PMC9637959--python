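"""Ideotype construction, the genotype x environment x management factorial
engine, rainfall-class environment clustering, drought-impact quantification
and variance-based sensitivity indices.

An ideotype is a baseline cultivar with its physiological traits (individual
leaf size, RUE, HI rate) scaled jointly by a multiplier; phenology is left
untouched.  The factorial engine runs one season simulation per combination
of site-year x time of sowing x stubble x row spacing x genotype and returns
a tidy table.  Main and total effects are the variance-decomposition indices
ME_i = Var(E[Y|X_i]) / Var(Y) and TE_i = 1 - Var(E[Y|X_{-i}]) / Var(Y),
computed with population moments on (ideally balanced) full factorials.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .canopy import simulate_season
from .io_formats import ManagementConfig
from .phenology import CultivarCoefficients

#: the sowing-date factor levels (month, day): late April to late June
DEFAULT_TOS = ((4, 28), (5, 12), (5, 26), (6, 7), (6, 23))
DEFAULT_STUBBLE = (0.0, 6.0)          # t/ha initial wheat residue
DEFAULT_SPACINGS = (190.0, 380.0)     # mm rows
DEFAULT_LEVELS = (1.1, 1.2, 1.3, 1.4)
IDEOTYPE_TRAITS = ("leaf_size", "rue", "hi_rate")

FACTOR_COLUMNS = ["tos", "stubble", "row_spacing", "genotype"]


@dataclass(frozen=True)
class Ideotype:
    """A named trait-multiplier design over a baseline cultivar."""

    name: str
    baseline: str
    trait_multipliers: dict

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.trait_multipliers.values()):
            raise ValueError("trait multipliers must be > 0")


def apply_ideotype(base: CultivarCoefficients,
                   ideotype: Ideotype) -> CultivarCoefficients:
    """Derived coefficients: physiological traits scaled, phenology untouched."""
    m = ideotype.trait_multipliers
    updates: dict = {"name": ideotype.name}
    if "leaf_size" in m:
        updates["leaf_size_node8"] = base.leaf_size_node8 * m["leaf_size"]
        updates["leaf_size_node14"] = base.leaf_size_node14 * m["leaf_size"]
    if "rue" in m:
        updates["rue"] = base.rue * m["rue"]
    if "hi_rate" in m:
        updates["hi_rate"] = base.hi_rate * m["hi_rate"]
    return dataclasses.replace(base, **updates)


def build_ideotypes(baselines, levels=DEFAULT_LEVELS, joint: bool = True
                    ) -> list[tuple[Ideotype, CultivarCoefficients]]:
    """Ideotypes from trait increments over baseline cultivars.

    ``joint=True`` (default) applies each multiplier to leaf size, RUE and HI
    rate together: len(baselines) x len(levels) ideotypes (2 x 4 = 8 at the
    defaults).  ``joint=False`` varies one trait at a time instead.
    """
    if not baselines:
        raise ValueError("need at least one baseline cultivar")
    out = []
    for base in baselines:
        for level in levels:
            if level <= 0:
                raise ValueError("ideotype multiplier must be > 0")
            if joint:
                ide = Ideotype(f"{base.name}_x{level:g}", base.name,
                               {t: level for t in IDEOTYPE_TRAITS})
                out.append((ide, apply_ideotype(base, ide)))
            else:
                for trait in IDEOTYPE_TRAITS:
                    ide = Ideotype(f"{base.name}_{trait}_x{level:g}",
                                   base.name, {trait: level})
                    out.append((ide, apply_ideotype(base, ide)))
    return out


def design_cells(n_sites: int, n_years: int) -> int:
    """Number of environment cells (site x year) in a design."""
    return n_sites * n_years


def run_factorial(sites, tos_dates=DEFAULT_TOS, stubble_levels=DEFAULT_STUBBLE,
                  spacings=DEFAULT_SPACINGS, genotypes=None,
                  engine=simulate_season, sowing_depth: float = 50.0,
                  density: float = 120.0, **engine_kwargs) -> pd.DataFrame:
    """Run the full factorial and return the tidy scenario table.

    ``sites`` is a list of dicts with keys ``site`` (name), ``weather`` (a
    multi-year WeatherSeries) and ``soil`` (SoilProfile); ``genotypes`` maps
    label -> CultivarCoefficients.  One engine run per site-year x TOS x
    stubble x spacing x genotype; failed seasons are flagged rows (yield NaN),
    never dropped.  Growing-season rainfall (sowing to maturity) is recorded
    per row.
    """
    if genotypes is None or not len(genotypes):
        raise ValueError("genotypes must be a non-empty mapping")
    for name, levels in [("tos_dates", tos_dates),
                         ("stubble_levels", stubble_levels),
                         ("spacings", spacings), ("sites", sites)]:
        if not len(levels):
            raise ValueError(f"{name} must be non-empty")
    rows = []
    for site in sites:
        weather, soil = site["weather"], site["soil"]
        years = sorted(weather.frame["date"].dt.year.unique())
        for year, (month, day), stubble, spacing, (glabel, cultivar) in \
                itertools.product(years, tos_dates, stubble_levels, spacings,
                                  genotypes.items()):
            sowing = dt.date(int(year), month, day)
            if pd.Timestamp(sowing) > weather.frame["date"].iloc[-1]:
                continue
            mgmt = ManagementConfig(sowing_date=sowing,
                                    sowing_depth=sowing_depth,
                                    density=density, row_spacing=spacing,
                                    initial_residue=stubble)
            season = weather.window(sowing, dt.date(int(year), 12, 31))
            res = engine(season, soil, cultivar, mgmt, **engine_kwargs)
            summary = res.summary
            if res.failed:
                yield_t_ha = np.nan
                gsr = summary["in_season_rain_mm"]
            else:
                yield_t_ha = summary["final_yield_t_ha"]
                mature = summary["maturity_date"]
                gsr = float(season.frame.loc[
                    season.frame["date"] <= mature, "rain"].sum())
            rows.append({
                "site": site["site"], "year": int(year),
                "decade": int(year) // 10 * 10,
                "tos": f"{month:02d}-{day:02d}", "stubble": stubble,
                "row_spacing": spacing, "genotype": glabel,
                "yield_t_ha": yield_t_ha,
                "paw_at_sowing_mm": summary["paw_at_sowing_mm"],
                "gsr_mm": gsr, "failed": res.failed,
            })
    return pd.DataFrame(rows)


def classify_environments(table: pd.DataFrame,
                          cutpoints=(100 / 3, 200 / 3)) -> pd.DataFrame:
    """Label every row with its environment cell's rainfall class.

    An environment cell is a site-year; its growing-season rainfall is the
    mean gsr over the cell's rows.  Cells are split at the given percentiles
    of cell gsr (terciles by default) into low/medium/high.  Returns a copy
    of the table with a ``rainfall_class`` column.
    """
    if "gsr_mm" not in table.columns:
        raise ValueError("table has no gsr_mm column")
    cell_gsr = table.groupby(["site", "year"])["gsr_mm"].mean()
    if cell_gsr.nunique() < 3:
        raise ValueError("need at least 3 distinct environment gsr values")
    lo, hi = np.percentile(cell_gsr, cutpoints)
    labels = pd.cut(cell_gsr, [-np.inf, lo, hi, np.inf],
                    labels=["low", "medium", "high"]).astype(str)
    out = table.copy()
    out["rainfall_class"] = labels.reindex(
        pd.MultiIndex.from_frame(out[["site", "year"]])).to_numpy()
    return out


def drought_impact(table: pd.DataFrame, group_by=("decade", "genotype"),
                   management=("stubble", "row_spacing"),
                   response: str = "yield_t_ha",
                   reference_filter: dict | None = None) -> pd.DataFrame:
    """Percent yield loss per group relative to the high-rainfall mean.

    By default the reference is the mean response over high-rainfall-class
    rows at the same genotype x management combination; loss% = (1 -
    mean/reference) x 100, so gains show as negative losses.

    ``reference_filter`` fixes reference columns to given values (e.g.
    ``{"genotype": "baseline", "stubble": 0.0}``) so that all groups are
    compared against a *common* baseline strategy's high-rainfall yield —
    the convention for quantifying how a strategy mitigates drought relative
    to current practice.
    """
    if "rainfall_class" not in table.columns:
        raise ValueError("run classify_environments first")
    reference_filter = reference_filter or {}
    ref_keys = [k for k in ("genotype", *management)
                if k in table.columns and k not in reference_filter]
    high = table[table["rainfall_class"] == "high"]
    for col, val in reference_filter.items():
        high = high[high[col] == val]
    if high.empty:
        raise ValueError("no high-rainfall environments in the reference set")
    merged = table.copy()
    if ref_keys:
        reference = high.groupby(ref_keys)[response].mean().rename("reference")
        merged = merged.merge(reference, left_on=ref_keys, right_index=True)
    else:
        merged["reference"] = high[response].mean()
    keys = [k for k in dict.fromkeys((*group_by, *management))
            if k in merged.columns]
    grouped = merged.groupby(keys).apply(
        lambda g: (1.0 - g[response].mean() / g["reference"].mean()) * 100.0,
        include_groups=False)
    return grouped.rename("loss_pct").reset_index()


def _check_variance(y: np.ndarray) -> float:
    var = float(np.var(y))
    if var == 0:
        raise ValueError("response has zero variance")
    return var


def _warn_if_unbalanced(counts) -> None:
    if counts.nunique() > 1:
        warnings.warn("design is unbalanced; conditional means are weighted "
                      "by group counts")


def main_effect(table: pd.DataFrame, factor: str,
                response: str = "yield_t_ha") -> float:
    """ME_i = Var(E[Y | X_i]) / Var(Y), population moments, count-weighted."""
    data = table.dropna(subset=[response])
    y = data[response].to_numpy(float)
    var_y = _check_variance(y)
    _warn_if_unbalanced(data.groupby(factor, observed=True)[response].count())
    cond = data.groupby(factor, observed=True)[response].transform("mean")
    return float(np.var(cond.to_numpy(float)) / var_y)


def total_effect(table: pd.DataFrame, factor: str,
                 response: str = "yield_t_ha",
                 factors=None) -> float:
    """TE_i = 1 - Var(E[Y | X_{-i}]) / Var(Y) over the complementary factors.

    ``factors`` lists all design factors (defaults to the standard scenario
    columns present in the table plus site/year environment factors).
    """
    if factors is None:
        factors = [c for c in (*FACTOR_COLUMNS, "site", "year")
                   if c in table.columns]
    others = [f for f in factors if f != factor]
    if not others:
        return 1.0  # single-factor design: everything is the factor's effect
    data = table.dropna(subset=[response])
    y = data[response].to_numpy(float)
    var_y = _check_variance(y)
    cond = data.groupby(others, observed=True)[response].transform("mean")
    return float(1.0 - np.var(cond.to_numpy(float)) / var_y)


def sensitivity_indices(table: pd.DataFrame, factors,
                        response: str = "yield_t_ha") -> pd.DataFrame:
    """Main and total effect per factor, plus the output variance."""
    data = table.dropna(subset=[response])
    var_y = _check_variance(data[response].to_numpy(float))
    rows = [{"factor": f,
             "main_effect": main_effect(data, f, response),
             "total_effect": total_effect(data, f, response, factors=factors),
             "var_y": var_y}
            for f in factors]
    return pd.DataFrame(rows)
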