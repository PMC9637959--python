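"""Synthetic weather, soils and field-trial observations with known ground
truth, emulating the south-eastern Australian semi-arid cropping environment:
winter-dominant rainfall in three annual-total classes (low < 300 mm, medium
300-450 mm, high > 450 mm), a wet early season and a dry spring finish.

Rainfall is a first-order two-state (wet/dry) occurrence chain with gamma
amounts, seasonally modulated so the configured fraction of rain falls in
April-October; temperature and radiation follow seasonal sinusoids (southern
hemisphere phase) plus bounded noise.  Every generator takes an explicit
integer seed; one global seed is split into independent per-stream seeds via
``numpy.random.SeedSequence.spawn``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .canopy import SimulationResult, simulate_season
from .io_formats import ManagementConfig, SoilProfile, WeatherSeries
from .phenology import CultivarCoefficients

WINTER_MONTHS = (4, 5, 6, 7, 8, 9, 10)  # Apr-Oct growing season


@dataclass(frozen=True)
class ClimateClassParams:
    """Parameters of one rainfall-class climate."""

    class_label: str                    # low | medium | high
    annual_rain_mean: float             # mm/year
    winter_fraction: float = 0.70       # share of rain in Apr-Oct
    temp_annual_mean: float = 16.0      # degC
    temp_amplitude: float = 7.0         # degC seasonal half-range
    diurnal_range: float = 11.0         # degC mean tmax - tmin
    radn_mean: float = 16.0             # MJ/m2/day annual mean
    radn_amplitude: float = 8.0         # MJ/m2/day seasonal half-range

    def __post_init__(self) -> None:
        if self.annual_rain_mean <= 0:
            raise ValueError("annual_rain_mean must be > 0")
        if not 0 < self.winter_fraction < 1:
            raise ValueError("winter_fraction must be in (0, 1)")


#: the three rainfall classes: low (<300 mm), medium (300-450 mm), high (>450)
CLIMATE_CLASSES: dict[str, ClimateClassParams] = {
    "low": ClimateClassParams("low", 250.0, temp_annual_mean=17.0),
    "medium": ClimateClassParams("medium", 375.0, temp_annual_mean=16.0),
    "high": ClimateClassParams("high", 550.0, temp_annual_mean=15.0),
}

# rainfall occurrence-chain settings (wet-day stationary probability and
# wet-after-wet persistence), winter vs summer
_PI_WET = {"winter": 0.35, "summer": 0.12}
_P_WW = {"winter": 0.55, "summer": 0.35}
_GAMMA_SHAPE = 0.75


def _season_of(month: np.ndarray) -> np.ndarray:
    return np.isin(month, WINTER_MONTHS)


def generate_weather(params: ClimateClassParams, n_years: int, seed: int,
                     site_id: str | None = None,
                     start_year: int = 2000) -> WeatherSeries:
    """Generate ``n_years`` of daily weather for one climate class.

    Deterministic for identical (params, n_years, seed).  Daily rain
    expectation integrates to ``annual_rain_mean`` with ``winter_fraction``
    of it in April-October.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    dates = pd.date_range(dt.date(start_year, 1, 1),
                          dt.date(start_year + n_years - 1, 12, 31), freq="D")
    doy = dates.dayofyear.to_numpy()
    month = dates.month.to_numpy()
    n = len(dates)

    # temperature: southern-hemisphere sinusoid (warmest mid January, doy 15)
    phase = 2 * np.pi * (doy - 15) / 365.25
    tmean = params.temp_annual_mean + params.temp_amplitude * np.cos(phase)
    tmean = tmean + rng.normal(0.0, 1.5, n)
    half_range = np.maximum(0.5, params.diurnal_range / 2
                            + rng.normal(0.0, 1.0, n))
    tmax = tmean + half_range
    tmin = tmean - half_range

    radn = params.radn_mean + params.radn_amplitude * np.cos(phase)
    radn = np.clip(radn + rng.normal(0.0, 2.0, n), 0.5, None)

    # rainfall: two-state occurrence chain, gamma amounts, seasonal scaling
    winter = _season_of(month)
    pi_wet = np.where(winter, _PI_WET["winter"], _PI_WET["summer"])
    p_ww = np.where(winter, _P_WW["winter"], _P_WW["summer"])
    # wet-after-dry chosen so the chain's stationary wet probability is pi_wet
    p_wd = pi_wet * (1 - p_ww) / (1 - pi_wet)
    n_winter = int(winter[:365].sum())
    n_summer = 365 - n_winter
    daily_target = np.where(
        winter,
        params.annual_rain_mean * params.winter_fraction / n_winter,
        params.annual_rain_mean * (1 - params.winter_fraction) / n_summer)
    mean_amount = daily_target / pi_wet  # mm per wet day
    u = rng.random(n)
    wet = np.zeros(n, dtype=bool)
    wet[0] = u[0] < pi_wet[0]
    for i in range(1, n):
        wet[i] = u[i] < (p_ww[i] if wet[i - 1] else p_wd[i])
    amounts = rng.gamma(_GAMMA_SHAPE, mean_amount / _GAMMA_SHAPE)
    rain = np.where(wet, np.round(amounts, 1), 0.0)

    frame = pd.DataFrame({"date": dates, "tmax": np.round(tmax, 1),
                          "tmin": np.round(tmin, 1), "rain": rain,
                          "radn": np.round(radn, 1)})
    return WeatherSeries(site_id or f"synthetic_{params.class_label}", frame)


#: layer thicknesses (mm) mirroring a 0-130 cm sampling scheme
DEFAULT_LAYER_THICKNESS = (150.0, 150.0, 200.0, 200.0, 200.0, 200.0, 200.0)


def generate_soil(pawc_target: float, n_layers: int = 7, seed: int = 0,
                  initial_fill: float = 0.25) -> SoilProfile:
    """A plausible clay profile with PAWC equal to ``pawc_target`` (mm).

    dul and ll15 increase gently with depth; the per-layer available range is
    scaled so sum((dul - ll15) x thickness) hits the target to within 0.5 mm.
    ``initial_fill`` sets initial_sw as a fraction of the available range;
    the default reflects a profile only partly recharged after a dry summer
    fallow, typical of semi-arid sowing conditions.
    """
    if pawc_target <= 0:
        raise ValueError("pawc_target must be > 0")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if n_layers <= len(DEFAULT_LAYER_THICKNESS):
        thickness = np.array(DEFAULT_LAYER_THICKNESS[:n_layers])
    else:
        thickness = np.full(n_layers, 200.0)
        thickness[:2] = 150.0
    total = thickness.sum()
    # feasibility: volumetric available range must stay below ~0.22
    if pawc_target / total > 0.22:
        raise ValueError(f"pawc_target {pawc_target} mm infeasible for "
                         f"{n_layers} layers ({total:.0f} mm deep)")
    ll15 = 0.10 + 0.06 * np.linspace(0, 1, n_layers) \
        + rng.uniform(-0.005, 0.005, n_layers)
    shape = 1.0 - 0.35 * np.linspace(0, 1, n_layers)  # capacity tapers down
    avail = shape / (shape * thickness).sum() * pawc_target
    dul = ll15 + avail
    sat = dul + 0.08
    bd = np.round(1.25 + 0.15 * np.linspace(0, 1, n_layers), 2)
    initial_sw = ll15 + initial_fill * (dul - ll15)
    from .io_formats import _default_kl
    return SoilProfile(thickness, dul, ll15, sat, bd,
                       swcon=np.full(n_layers, 0.3), kl=_default_kl(n_layers),
                       initial_sw=initial_sw)


@dataclass(frozen=True)
class TrialObservations:
    """One parameterization trial's observation bundle.

    ``stage_dates`` maps stage name -> calendar date; ``biomass_series`` and
    ``hi_series`` are (days_after_sowing, value) pairs from six harvests in
    grain fill; ``par_pairs`` are fortnightly (date, incident, transmitted)
    ceptometer readings (umol/m2/s); ``node_series`` are weekly (degCd since
    emergence, mainstem node number) counts; ``emergence_trials`` are
    (sowing depth mm, degCd at 50% emergence) pairs.
    """

    stage_dates: dict[str, dt.date]
    biomass_series: tuple[tuple[float, float], ...]
    hi_series: tuple[tuple[float, float], ...]
    par_pairs: tuple[tuple[dt.date, float, float], ...]
    node_series: tuple[tuple[float, float], ...]
    emergence_trials: tuple[tuple[float, float], ...] = ()
    sowing_date: dt.date | None = None


#: observation noise defaults (standard deviations); keys match generate_trial
DEFAULT_NOISE = {
    "stage_days": 1.0,     # additive days on stage dates
    "biomass_rel": 0.05,   # multiplicative log-normal on biomass
    "hi": 0.005,           # additive on harvest index
    "par_rel": 0.02,       # multiplicative on transmitted PAR
    "node": 0.25,          # additive on node counts
}

ZERO_NOISE = {k: 0.0 for k in DEFAULT_NOISE}


def generate_trial(cultivar: CultivarCoefficients, weather: WeatherSeries,
                   soil: SoilProfile, mgmt: ManagementConfig,
                   noise_sd: dict | None = None, seed: int = 0,
                   well_watered: bool = True, replicates: int = 3,
                   ) -> tuple[TrialObservations, SimulationResult]:
    """Forward-simulate a parameterization trial and sample its observations.

    Schedule mirrors the field protocol: six biomass/HI harvest dates between
    the start of grain fill and maturity, each cut in ``replicates``
    independent plots (trials were replicated three times), fortnightly
    ceptometer readings from emergence, weekly node counts from emergence to
    flowering.  With all-zero noise the observations are exactly consistent
    with the generating coefficients.  Returns (observations, the underlying
    simulation).
    """
    noise = dict(DEFAULT_NOISE, **(noise_sd or {}))
    streams = np.random.SeedSequence(seed).spawn(5)
    res = simulate_season(weather, soil, cultivar, mgmt,
                          well_watered=well_watered)
    if res.failed:
        raise RuntimeError("trial crop failed to reach maturity; "
                           f"stage reached: {res.stage_reached}")
    daily = res.daily.set_index("date")
    sdates = res.summary["stage_dates"]
    sowing = pd.Timestamp(mgmt.sowing_date)

    rng = np.random.default_rng(streams[0])
    stage_dates = {}
    for name, time in res.summary["stage_times"].items():
        if noise["stage_days"]:
            # field records are calendar days with observation error
            jitter = round(float(rng.normal(0.0, noise["stage_days"])))
            stage_dates[name] = (time.normalize()
                                 + pd.Timedelta(days=jitter)).date()
        else:
            # noiseless records keep the thermal clock's sub-daily crossing
            stage_dates[name] = time

    # six harvests, start of grain fill -> maturity
    rng = np.random.default_rng(streams[1])
    start_gf, maturity = sdates["start_grain_fill"], sdates["maturity"]
    harvest_dates = pd.to_datetime(
        np.linspace(start_gf.value, maturity.value, 6).astype("int64")).normalize()
    biomass_series, hi_series = [], []
    for d in harvest_dates:
        das = (d - sowing).days
        for _ in range(replicates):
            bio = daily.loc[d, "biomass"]
            hi = daily.loc[d, "hi"]
            if noise["biomass_rel"]:
                bio *= float(np.exp(rng.normal(0.0, noise["biomass_rel"])))
            if noise["hi"]:
                hi = float(np.clip(hi + rng.normal(0.0, noise["hi"]),
                                   0.0, 1.0))
            biomass_series.append((float(das), float(bio)))
            hi_series.append((float(das), float(hi)))

    # fortnightly ceptometer pairs from emergence to maturity
    rng = np.random.default_rng(streams[2])
    par_pairs = []
    emergence = sdates["emergence"]
    d = emergence
    incident = 2000.0  # umol/m2/s, midday clear-sky reference
    while d <= maturity:
        fipar = float(daily.loc[d, "fipar"])
        transmitted = incident * (1.0 - fipar)
        if noise["par_rel"]:
            transmitted = float(np.clip(
                transmitted * np.exp(rng.normal(0.0, noise["par_rel"])),
                0.0, incident))
        par_pairs.append((d.date(), incident, transmitted))
        d += pd.Timedelta(days=14)

    # weekly node counts, emergence to flowering, against the observer's own
    # cumulative degCd clock (counted from the emergence date)
    rng = np.random.default_rng(streams[3])
    flowering = sdates["flowering"]
    node_rows = []
    tt_cum = 0.0
    next_obs = emergence
    for row in res.daily.itertuples(index=False):
        if row.date < emergence or row.date >= flowering:
            continue
        if row.date > emergence:
            tt_cum += row.tt
        if row.date >= next_obs:
            node = float(row.nodes)
            if noise["node"]:
                node = max(0.0, node + rng.normal(0.0, noise["node"]))
            node_rows.append((tt_cum, node))
            next_obs = row.date + pd.Timedelta(days=7)

    obs = TrialObservations(
        stage_dates=stage_dates,
        biomass_series=tuple(biomass_series),
        hi_series=tuple(hi_series),
        par_pairs=tuple(par_pairs),
        node_series=tuple(node_rows),
        sowing_date=mgmt.sowing_date,
    )
    return obs, res


def generate_emergence_trials(lag: float, rate: float, depths,
                              noise_sd: float = 0.0, seed: int = 0
                              ) -> list[tuple[float, float]]:
    """Per sowing depth, the cumulative thermal time (degCd) at 50% emergence:
    lag + rate x depth, plus optional Gaussian noise."""
    depths = list(depths)
    if not depths:
        raise ValueError("depths must be non-empty")
    if any(d < 0 for d in depths):
        raise ValueError("depths must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = []
    for d in depths:
        tt = lag + rate * d
        if noise_sd:
            tt += float(rng.normal(0.0, noise_sd))
        out.append((float(d), float(tt)))
    return out
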