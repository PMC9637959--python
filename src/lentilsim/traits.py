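"""Cultivar parameterization: turn trial observations into coefficients.

Every estimator is the field procedure itself — an ordinary least-squares
slope (free intercept) of the relevant pair of observables:

* RUE: aboveground biomass vs cumulative intercepted radiation,
* HI rate: harvest index vs days after sowing (the x-intercept estimates the
  start of grain fill),
* node appearance rate: the reciprocal slope of node number vs degCd,
* shoot lag / shoot rate: intercept and slope of emergence degCd vs depth,
* phase durations: daily thermal time summed between observed stage dates.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import WeatherSeries
from .phenology import CultivarCoefficients, ThermalResponse, daily_thermal_time

#: published lentil HI-rate band (fraction/day) used for plausibility flags
HI_RATE_PLAUSIBLE_BAND = (0.0090, 0.0139)


class DegenerateDesignError(ValueError):
    """The regression design is degenerate (constant regressor)."""


@dataclass(frozen=True)
class CeptometerReading:
    """One paired ceptometer measurement (umol/m2/s)."""

    date: dt.date
    incident: float
    transmitted: float

    def __post_init__(self) -> None:
        if self.incident <= 0:
            raise ValueError("incident PAR must be > 0")
        if not 0 <= self.transmitted <= self.incident:
            raise ValueError("transmitted PAR must lie in [0, incident]")


@dataclass(frozen=True)
class CoefficientEstimate:
    """An estimated coefficient with its OLS uncertainty."""

    value: float
    stderr: float
    n: int
    r_squared: float
    intercept: float = 0.0
    plausible: bool | None = None

    def __post_init__(self) -> None:
        if self.stderr < 0:
            raise ValueError("stderr must be >= 0")


def _ols(x, y) -> tuple:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 2 or np.ptp(x) == 0:
        raise DegenerateDesignError("regressor is constant or too short")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # r undefined for constant y
        res = stats.linregress(x, y)
    r2 = 0.0 if np.isnan(res.rvalue) else float(res.rvalue**2)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return float(res.slope), float(res.intercept), stderr, r2, len(x)


def compute_fipar(reading: CeptometerReading) -> float:
    """Fraction of intercepted PAR: 1 - transmitted/incident."""
    return 1.0 - reading.transmitted / reading.incident


def cumulative_ipar(weather: WeatherSeries, fipar_series,
                    emergence_date: dt.date | None = None) -> pd.Series:
    """Running sum of daily radiation x fiPAR, indexed by date (MJ/m2).

    ``fipar_series`` maps reading date -> fiPAR (a dict or (date, fipar)
    pairs).  fiPAR is interpolated linearly in time between readings, ramps
    from 0 at ``emergence_date`` (default: first weather date) up to the
    first reading, and holds constant after the last.
    """
    if isinstance(fipar_series, dict):
        pairs = sorted(fipar_series.items())
    else:
        pairs = sorted(fipar_series)
    if not pairs:
        raise ValueError("fipar_series is empty")
    values = np.array([v for _, v in pairs], float)
    if ((values < 0) | (values > 1)).any():
        raise ValueError("fiPAR values must lie in [0, 1]")
    dates = [pd.Timestamp(d) for d, _ in pairs]
    frame = weather.frame
    start = pd.Timestamp(emergence_date) if emergence_date else frame["date"].iloc[0]
    if start < dates[0]:
        dates = [start] + dates
        values = np.concatenate([[0.0], values])
    xp = np.array([d.value for d in dates], float)
    x = frame["date"].astype("int64").to_numpy().astype(float)
    fipar_daily = np.interp(x, xp, values)
    fipar_daily[frame["date"] < start] = 0.0
    cum = np.cumsum(frame["radn"].to_numpy() * fipar_daily)
    return pd.Series(cum, index=frame["date"], name="cum_ipar")


def estimate_rue(biomass_series, cum_ipar) -> CoefficientEstimate:
    """RUE (g/MJ): OLS slope of biomass (g/m2) on cumulative iPAR (MJ/m2).

    ``biomass_series`` is (days_after_sowing, biomass) pairs or a 2-column
    array; ``cum_ipar`` gives the matching cumulative iPAR per point — either
    a sequence aligned with the biomass points or a date-indexed Series plus
    day offsets resolved by the caller.
    """
    bio = np.asarray([b for _, b in biomass_series], float)
    x = np.asarray(cum_ipar, float)
    if len(x) != len(bio):
        raise ValueError("biomass and cum_ipar lengths differ")
    if len(x) < 3:
        raise ValueError("need at least 3 paired points")
    slope, intercept, stderr, r2, n = _ols(x, bio)
    return CoefficientEstimate(slope, stderr, n, r2, intercept)


def estimate_hi_rate(hi_series) -> CoefficientEstimate:
    """HI rate (fraction/day): OLS slope of harvest index on days after sowing.

    The fitted line's x-intercept estimates the start of grain fill (days
    after sowing) and is reported in ``intercept``.  ``plausible`` flags
    whether the slope falls in the published lentil band.
    """
    days = np.asarray([d for d, _ in hi_series], float)
    hi = np.asarray([h for _, h in hi_series], float)
    if len(days) < 3:
        raise ValueError("need at least 3 harvests")
    slope, intercept, stderr, r2, n = _ols(days, hi)
    x_intercept = -intercept / slope if slope != 0 else float("nan")
    lo, hi_band = HI_RATE_PLAUSIBLE_BAND
    plausible = bool(lo <= slope <= hi_band)
    if not plausible:
        warnings.warn(f"estimated HI rate {slope:.4g}/day is outside the "
                      f"published lentil band [{lo}, {hi_band}]")
    return CoefficientEstimate(slope, stderr, n, r2, x_intercept, plausible)


def estimate_node_rate(node_series) -> CoefficientEstimate:
    """Node appearance rate (degCd/node): reciprocal OLS slope of node number
    on cumulative degCd since emergence."""
    tt = np.asarray([t for t, _ in node_series], float)
    nodes = np.asarray([n for _, n in node_series], float)
    if len(tt) < 3:
        raise ValueError("need at least 3 node counts")
    if (np.diff(nodes) < 0).any():
        raise ValueError("node counts must be non-decreasing")
    slope, intercept, stderr, r2, n = _ols(tt, nodes)
    if slope <= 0:
        raise DegenerateDesignError("node counts do not increase with degCd")
    rate = 1.0 / slope
    # delta-method standard error of the reciprocal
    return CoefficientEstimate(rate, stderr / slope**2, n, r2, intercept)


def estimate_phase_tt(stage_dates: dict, weather: WeatherSeries,
                      resp: ThermalResponse = ThermalResponse()) -> dict:
    """Cumulative degCd between consecutive observed stage times.

    Returns {'stage_a_to_stage_b': degCd, ...} in chronological order.  Stage
    times may carry a sub-daily fraction (the thermal clock's crossing time);
    the boundary days then contribute that fraction of their thermal time.
    For whole-day records a phase sums daily values from its start date
    (inclusive) up to, but excluding, its end date.
    """
    items = sorted(stage_dates.items(), key=lambda kv: pd.Timestamp(kv[1]))
    times = [pd.Timestamp(t) for _, t in items]
    frame = weather.frame
    if (times[0].normalize() < frame["date"].iloc[0]
            or times[-1].normalize() > frame["date"].iloc[-1]):
        raise ValueError("weather does not cover the stage dates")
    tt = pd.Series(
        [daily_thermal_time(r.tmax, r.tmin, resp)
         for r in frame.itertuples(index=False)],
        index=frame["date"])

    def cum_tt_at(t: pd.Timestamp) -> float:
        """degCd accumulated from the series start up to thermal-clock time t."""
        day = t.normalize()
        frac = (t - day) / pd.Timedelta(days=1)
        return float(tt.loc[:day - pd.Timedelta(days=1)].sum()
                     + frac * tt.loc[day])

    out = {}
    for (name_a, _), (name_b, _), a, b in zip(items[:-1], items[1:],
                                              times[:-1], times[1:]):
        out[f"{name_a}_to_{name_b}"] = cum_tt_at(b) - cum_tt_at(a)
    return out


def estimate_shoot_params(emergence_trials) -> tuple[float, float]:
    """(shoot_lag degCd, shoot_rate degCd/mm) from (depth, emergence degCd)
    pairs: OLS intercept and slope."""
    depths = np.asarray([d for d, _ in emergence_trials], float)
    tts = np.asarray([t for _, t in emergence_trials], float)
    if len(set(depths.tolist())) < 2:
        raise DegenerateDesignError("need at least two distinct sowing depths")
    slope, intercept, *_ = _ols(depths, tts)
    return float(intercept), float(slope)


def calibrate_cultivar(obs, weather: WeatherSeries,
                       base: CultivarCoefficients) -> CultivarCoefficients:
    """Full calibration: estimate every estimable coefficient from a trial's
    observations and return a copy of ``base`` with them filled in.

    Phase durations come from observed stage dates; node rate, HI rate and
    RUE from their regressions; shoot lag/rate from emergence trials when
    present.  Leaf sizes and hi_max are direct measurements outside this
    observation bundle and are carried over from ``base``.
    """
    updates: dict = {}
    phases = estimate_phase_tt(obs.stage_dates, weather, base.thermal)

    def phase(a, b):
        return phases.get(f"{a}_to_{b}")

    mapping = {
        "tt_emerg_to_endjuv": phase("emergence", "end_of_juvenile"),
        "tt_endjuv_to_init": phase("end_of_juvenile", "floral_initiation"),
        "tt_init_to_flower": phase("floral_initiation", "flowering"),
        "tt_flower_to_start_grain": phase("flowering", "start_grain_fill"),
        "tt_start_to_end_grain": phase("start_grain_fill", "end_grain_fill"),
        "tt_end_grain_to_maturity": phase("end_grain_fill", "maturity"),
    }
    updates.update({k: v for k, v in mapping.items() if v})

    if obs.node_series:
        updates["node_app_rate"] = estimate_node_rate(obs.node_series).value
    if obs.hi_series:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            updates["hi_rate"] = estimate_hi_rate(obs.hi_series).value
    if obs.par_pairs and obs.biomass_series:
        fipar_by_date = {d: 1.0 - tr / inc for d, inc, tr in obs.par_pairs}
        cum = cumulative_ipar(weather, fipar_by_date,
                              emergence_date=obs.stage_dates.get("emergence"))
        sowing = pd.Timestamp(obs.sowing_date or weather.frame["date"].iloc[0])
        x = [float(cum.loc[sowing + pd.Timedelta(days=int(das))])
             for das, _ in obs.biomass_series]
        updates["rue"] = estimate_rue(obs.biomass_series, x).value
    if obs.emergence_trials:
        lag, rate = estimate_shoot_params(obs.emergence_trials)
        updates["shoot_lag"] = lag
        updates["shoot_rate"] = rate
    return replace(base, **updates)
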