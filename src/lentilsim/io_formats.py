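"""On-disk formats for weather, soil, cultivar, management and results tables.

Weather is accepted in two dialects: a plain CSV (``date,tmax,tmin,rain,radn``,
ISO dates) and an APSIM ``.met``-style text file (section header, ``site =``
lines, a column line, a units line in parentheses, then whitespace-separated
``year day`` rows).  The internal model is the CSV semantics; ``.met`` unit
strings are *checked*, never converted.

Soil, cultivar and management configuration are YAML.  Depths/thicknesses are
millimetres internally; a soil file may declare ``units: {thickness: cm}`` and
is converted on read.  Volumetric water contents are fractions (mm3/mm3).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml


class FormatError(ValueError):
    """A file does not follow the declared dialect (missing column, bad units)."""


class ValidationError(ValueError):
    """Parsed content breaches a domain invariant (e.g. tmax < tmin)."""


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

WEATHER_COLUMNS = ["date", "tmax", "tmin", "rain", "radn"]
_COLUMN_SYNONYMS = {"maxt": "tmax", "mint": "tmin", "date": "date",
                    "tmax": "tmax", "tmin": "tmin", "rain": "rain", "radn": "radn"}
_MET_EXPECTED_UNITS = {"radn": "(mj/m^2)", "maxt": "(oc)", "mint": "(oc)",
                       "rain": "(mm)", "year": "()", "day": "()"}


@dataclass(frozen=True)
class WeatherSeries:
    """Validated daily weather: date, tmax/tmin (degC), rain (mm), radn (MJ/m2)."""

    site_id: str
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in WEATHER_COLUMNS if c not in f.columns]
        if missing:
            raise FormatError(f"weather table missing column(s): {missing}")
        f = f.loc[:, WEATHER_COLUMNS].reset_index(drop=True)
        f["date"] = pd.to_datetime(f["date"])
        deltas = f["date"].diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            i = int(np.argmax(deltas.to_numpy() <= pd.Timedelta(0).to_timedelta64()))
            raise ValidationError(f"dates not strictly increasing at row {i + 1}")
        if (deltas != pd.Timedelta(days=1)).any():
            i = int(np.argmax(deltas.to_numpy() != pd.Timedelta(days=1).to_timedelta64()))
            raise ValidationError(f"date gap at row {i + 1}")
        bad = f["tmax"] < f["tmin"]
        if bad.any():
            raise ValidationError(f"tmax < tmin at row {int(bad.idxmax())}")
        for col in ("rain", "radn"):
            neg = f[col] < 0
            if neg.any():
                raise ValidationError(f"negative {col} at row {int(neg.idxmax())}")
        object.__setattr__(self, "frame", f)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.Series:
        return self.frame["date"]

    def window(self, start: dt.date, end: dt.date | None = None) -> "WeatherSeries":
        """Sub-series from ``start`` to ``end`` inclusive (end defaults to last)."""
        f = self.frame
        mask = f["date"] >= pd.Timestamp(start)
        if end is not None:
            mask &= f["date"] <= pd.Timestamp(end)
        return WeatherSeries(self.site_id, f.loc[mask].reset_index(drop=True))


def read_weather(path: str | Path, dialect: str | None = None) -> WeatherSeries:
    """Read a weather file; ``dialect`` is ``'met'``, ``'csv'`` or None (sniff)."""
    path = Path(path)
    if dialect is None:
        dialect = "met" if path.suffix.lower() == ".met" else "csv"
    if dialect == "csv":
        return _read_weather_csv(path)
    if dialect == "met":
        return _read_weather_met(path)
    raise ValueError(f"unknown weather dialect {dialect!r}")


def _read_weather_csv(path: Path) -> WeatherSeries:
    f = pd.read_csv(path)
    f.columns = [c.strip().lower() for c in f.columns]
    f = f.rename(columns=_COLUMN_SYNONYMS)
    if "date" not in f.columns and {"year", "day"} <= set(f.columns):
        f["date"] = _dates_from_year_doy(f["year"], f["day"])
    missing = [c for c in WEATHER_COLUMNS if c not in f.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return WeatherSeries(path.stem, f)


def _dates_from_year_doy(year, doy) -> pd.Series:
    return (pd.to_datetime(year.astype(int).astype(str), format="%Y")
            + pd.to_timedelta(doy.astype(int) - 1, unit="D"))


def _read_weather_met(path: Path) -> WeatherSeries:
    site = path.stem
    lines = path.read_text().splitlines()
    header_idx = None
    for i, line in enumerate(lines):
        s = line.strip().lower()
        if s.startswith("site"):
            parts = line.split("=", 1)
            if len(parts) == 2:
                site = parts[1].strip()
        tokens = s.split()
        if tokens and {"year", "day"} <= set(tokens):
            header_idx = i
            break
    if header_idx is None:
        raise FormatError(f"{path}: no 'year day ...' column line found")
    cols = lines[header_idx].split()
    units = lines[header_idx + 1].split()
    if len(units) != len(cols) or not all(u.startswith("(") for u in units):
        raise FormatError(f"{path}: units line malformed")
    for c, u in zip(cols, units):
        expected = _MET_EXPECTED_UNITS.get(c.lower())
        if expected is not None and u.lower() != expected:
            raise FormatError(f"{path}: column {c} has units {u}, expected {expected}")
    data_rows = [ln.split() for ln in lines[header_idx + 2:] if ln.strip()
                 and not ln.strip().startswith(("!", "["))]
    f = pd.DataFrame(data_rows, columns=[c.lower() for c in cols]).astype(float)
    f = f.rename(columns=_COLUMN_SYNONYMS)
    missing = [c for c in ("year", "day", "tmax", "tmin", "rain", "radn")
               if c not in f.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    f["date"] = _dates_from_year_doy(f["year"], f["day"])
    return WeatherSeries(site, f)


def write_weather(series: WeatherSeries, path: str | Path,
                  dialect: str | None = None) -> None:
    path = Path(path)
    if dialect is None:
        dialect = "met" if path.suffix.lower() == ".met" else "csv"
    f = series.frame
    if dialect == "csv":
        out = f.copy()
        out["date"] = out["date"].dt.strftime("%Y-%m-%d")
        out.to_csv(path, index=False)
        return
    if dialect != "met":
        raise ValueError(f"unknown weather dialect {dialect!r}")
    with open(path, "w") as fh:
        fh.write("[weather.met.weather]\n")
        fh.write(f"site = {series.site_id}\n")
        fh.write("year day radn maxt mint rain\n")
        fh.write("() () (MJ/m^2) (oC) (oC) (mm)\n")
        for _, r in f.iterrows():
            d = r["date"]
            fh.write(f"{d.year} {d.dayofyear} {r['radn']:.2f} "
                     f"{r['tmax']:.2f} {r['tmin']:.2f} {r['rain']:.2f}\n")


# ---------------------------------------------------------------------------
# Soil
# ---------------------------------------------------------------------------

def _default_kl(n: int) -> np.ndarray:
    # 0.06 in the top layer, decaying x0.9 per layer down the profile
    return 0.06 * 0.9 ** np.arange(n)


@dataclass(frozen=True)
class SoilProfile:
    """Layered water-holding limits.

    Per layer: thickness (mm), dul/ll15/sat (volumetric fractions), bd (g/cm3),
    swcon (drainage fraction/day), kl (uptake fraction/day), initial_sw
    (volumetric fraction).  ``u_evap`` (mm) limits stage-1 soil evaporation and
    ``cona`` (mm/day^0.5) sets the stage-2 rate.
    """

    thickness: np.ndarray
    dul: np.ndarray
    ll15: np.ndarray
    sat: np.ndarray
    bd: np.ndarray
    swcon: np.ndarray
    kl: np.ndarray
    initial_sw: np.ndarray
    u_evap: float = 6.0
    cona: float = 3.5

    def __post_init__(self) -> None:
        arrays = {}
        n = len(self.thickness)
        for f_ in dataclasses.fields(self):
            if f_.name in ("u_evap", "cona"):
                continue
            a = np.asarray(getattr(self, f_.name), dtype=float)
            if len(a) != n:
                raise ValidationError(
                    f"soil layer array {f_.name!r} has length {len(a)}, expected {n}")
            arrays[f_.name] = a
            object.__setattr__(self, f_.name, a)
        if n == 0:
            raise ValidationError("soil profile must have at least one layer")
        if (arrays["thickness"] <= 0).any():
            raise ValidationError("layer thickness must be > 0")
        for i in range(n):
            ll, du, sa = arrays["ll15"][i], arrays["dul"][i], arrays["sat"][i]
            if not (0 < ll < du < sa < 1):
                raise ValidationError(
                    f"layer {i}: need 0 < ll15 < dul < sat < 1, got "
                    f"ll15={ll}, dul={du}, sat={sa}")
            if not (ll <= arrays["initial_sw"][i] <= sa):
                raise ValidationError(f"layer {i}: initial_sw outside [ll15, sat]")
        for name in ("swcon", "kl"):
            if ((arrays[name] < 0) | (arrays[name] > 1)).any():
                raise ValidationError(f"{name} must lie in [0, 1]")

    @property
    def n_layers(self) -> int:
        return len(self.thickness)

    @property
    def total_depth(self) -> float:
        return float(self.thickness.sum())

    @property
    def depth_bottom(self) -> np.ndarray:
        return np.cumsum(self.thickness)

    @property
    def pawc(self) -> float:
        """Plant-available water capacity, sum((dul - ll15) * thickness), mm."""
        return float(((self.dul - self.ll15) * self.thickness).sum())


def read_soil(path: str | Path) -> SoilProfile:
    """Read a YAML soil profile; per-layer arrays must have equal length."""
    path = Path(path)
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict) or "layers" not in cfg:
        raise FormatError(f"{path}: expected a mapping with a 'layers' section")
    layers = cfg["layers"]
    if "thickness" not in layers or "dul" not in layers or "ll15" not in layers:
        raise FormatError(f"{path}: layers need thickness, dul and ll15")
    lengths = {k: len(v) for k, v in layers.items()}
    if len(set(lengths.values())) != 1:
        raise FormatError(f"{path}: unequal layer array lengths: {lengths}")
    n = lengths["thickness"]
    thickness = np.asarray(layers["thickness"], float)
    if cfg.get("units", {}).get("thickness", "mm") == "cm":
        thickness = thickness * 10.0
    dul = np.asarray(layers["dul"], float)
    ll15 = np.asarray(layers["ll15"], float)
    sat = np.asarray(layers.get("sat", dul + 0.08), float)
    bd = np.asarray(layers.get("bd", [1.3] * n), float)
    swcon = np.asarray(layers.get("swcon", [0.3] * n), float)
    kl = np.asarray(layers.get("kl", _default_kl(n)), float)
    initial_sw = np.asarray(layers.get("initial_sw", ll15 + 0.5 * (dul - ll15)), float)
    return SoilProfile(thickness, dul, ll15, sat, bd, swcon, kl, initial_sw,
                       u_evap=float(cfg.get("u_evap", 6.0)),
                       cona=float(cfg.get("cona", 3.5)))


def write_soil(profile: SoilProfile, path: str | Path) -> None:
    cfg = {
        "u_evap": float(profile.u_evap),
        "cona": float(profile.cona),
        "units": {"thickness": "mm"},
        "layers": {name: [float(x) for x in getattr(profile, name)]
                   for name in ("thickness", "dul", "ll15", "sat", "bd",
                                "swcon", "kl", "initial_sw")},
    }
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# ---------------------------------------------------------------------------
# Management
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManagementConfig:
    """Sowing and surface management for one season."""

    sowing_date: dt.date
    sowing_depth: float = 50.0          # mm
    density: float = 120.0              # plants/m2
    row_spacing: float = 190.0          # mm
    initial_residue: float = 0.0        # t/ha surface residue at sowing
    residue_type: str = "wheat"

    def __post_init__(self) -> None:
        if self.sowing_depth <= 0:
            raise ValidationError("sowing_depth must be > 0")
        if self.density <= 0:
            raise ValidationError("density must be > 0")
        if self.row_spacing <= 0:
            raise ValidationError("row_spacing must be > 0")
        if self.initial_residue < 0:
            raise ValidationError("initial_residue must be >= 0")


def read_management(path: str | Path) -> ManagementConfig:
    cfg = yaml.safe_load(Path(path).read_text())
    cfg["sowing_date"] = pd.Timestamp(cfg["sowing_date"]).date()
    return ManagementConfig(**cfg)


def write_management(mgmt: ManagementConfig, path: str | Path) -> None:
    cfg = dataclasses.asdict(mgmt)
    cfg["sowing_date"] = mgmt.sowing_date.isoformat()
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write a results table as UTF-8 CSV with stable column order.

    Deterministic byte output for a fixed table; empty tables are an error.
    """
    if hasattr(table, "daily"):  # SimulationResult duck-typing
        table = table.daily
    if not isinstance(table, pd.DataFrame):
        raise TypeError("write_results expects a DataFrame or SimulationResult")
    if table.empty:
        raise ValidationError("refusing to write an empty results table")
    out = table.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_results(path: str | Path) -> pd.DataFrame:
    f = pd.read_csv(path)
    if "date" in f.columns:
        f["date"] = pd.to_datetime(f["date"])
    return f
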