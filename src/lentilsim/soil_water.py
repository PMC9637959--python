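"""Layered soil water bucket: rain partitioning, two-stage evaporation with
residue cover, cascading drainage, root uptake and plant-available water.

The daily step composes, in order: rain partitioning (runoff reduced by
residue cover), cascading infiltration to saturation, drainage (swcon per
layer), two-stage soil evaporation (stage 1 up to ``u`` mm since the last
rewetting, stage 2 at cona x (sqrt(t) - sqrt(t-1))), and kl-limited root
uptake.  Mass is conserved to 1e-6 mm per day by construction and checked.
Unsaturated redistribution between layers is deliberately omitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import SoilProfile

#: fraction of ll15 the surface layer can dry below wilting point to (air-dry)
AIR_DRY_FACTOR = 0.5
#: residue area per mass for wheat stubble, ha/t
SPECIFIC_AREA_WHEAT = 0.4


@dataclass
class SoilWaterState:
    """Evolving per-layer water content plus evaporation-stage bookkeeping."""

    sw: np.ndarray                      # volumetric fraction per layer
    cum_evap_stage1: float = 0.0        # mm evaporated since last rewetting
    cum_evap_stage2: float = 0.0        # mm evaporated in stage 2
    days_in_stage2: int = 0
    residue_mass: float = 0.0           # t/ha surface residue

    def __post_init__(self) -> None:
        self.sw = np.asarray(self.sw, dtype=float).copy()
        if self.residue_mass < 0:
            raise ValueError("residue_mass must be >= 0")

    @classmethod
    def from_profile(cls, profile: SoilProfile,
                     residue_mass: float = 0.0) -> "SoilWaterState":
        return cls(sw=profile.initial_sw.copy(), residue_mass=residue_mass)

    def copy(self) -> "SoilWaterState":
        return SoilWaterState(self.sw.copy(), self.cum_evap_stage1,
                              self.cum_evap_stage2, self.days_in_stage2,
                              self.residue_mass)

    def storage(self, profile: SoilProfile) -> float:
        """Total stored water over the profile, mm."""
        return float((self.sw * profile.thickness).sum())


@dataclass(frozen=True)
class WaterFlux:
    """One day's water-balance components (all mm, all >= 0 except Δstorage)."""

    rain: float
    runoff: float
    infiltration: float
    drainage: float
    soil_evap: float
    uptake: float
    delta_storage: float


def residue_cover(mass: float, specific_area: float = SPECIFIC_AREA_WHEAT) -> float:
    """Fractional soil cover of a surface residue load (t/ha)."""
    if mass < 0:
        raise ValueError("residue mass must be >= 0")
    return 1.0 - float(np.exp(-specific_area * mass))


def partition_rain(rain: float, cover: float, runoff_coeff: float = 0.15,
                   runoff_threshold: float = 20.0) -> tuple[float, float]:
    """Split daily rain into (runoff, infiltration).

    Runoff only above ``runoff_threshold`` mm/day, scaled down by surface
    cover (full cover -> no runoff).
    """
    runoff = runoff_coeff * (1.0 - cover) * max(0.0, rain - runoff_threshold)
    return runoff, rain - runoff


def soil_evaporation(state: SoilWaterState, profile: SoilProfile, eos: float,
                     cover: float, u: float | None = None,
                     cona: float | None = None) -> float:
    """Evaporate from the top layer; two-stage, residue-limited.  Mutates state.

    ``eos`` is the potential at the soil surface (already shaded by canopy);
    residue reduces it by (1 - 0.8 x cover).  Stage 1 proceeds at potential
    until ``u`` mm have evaporated since the last rewetting; stage 2 follows a
    sqrt-time curve at rate ``cona``, with the elapsed stage-2 time carried
    implicitly as t = (cum_evap_stage2 / cona)^2 so that rewetting (which
    reduces the accumulators, see :func:`rewet_evaporation`) rewinds the
    curve.  Never dries the top layer below air-dry.
    """
    if eos < 0:
        raise ValueError("potential evaporation must be >= 0")
    u = profile.u_evap if u is None else u
    cona = profile.cona if cona is None else cona
    eos_r = eos * (1.0 - 0.8 * cover)
    if state.cum_evap_stage1 + eos_r <= u:
        evap = eos_r
        state.cum_evap_stage1 += eos_r
    else:
        stage1_part = max(0.0, u - state.cum_evap_stage1)
        state.cum_evap_stage1 = u
        t = (state.cum_evap_stage2 / cona) ** 2
        stage2 = cona * np.sqrt(t + 1) - state.cum_evap_stage2
        stage2 = min(stage2, eos_r - stage1_part)
        state.cum_evap_stage2 += stage2
        state.days_in_stage2 = int(np.ceil((state.cum_evap_stage2 / cona) ** 2))
        evap = stage1_part + stage2
    air_dry = AIR_DRY_FACTOR * profile.ll15[0]
    available = max(0.0, (state.sw[0] - air_dry) * profile.thickness[0])
    evap = min(evap, available)
    state.sw[0] -= evap / profile.thickness[0]
    return float(evap)


def rewet_evaporation(state: SoilWaterState, infiltration: float) -> None:
    """Rewind the two-stage evaporation accumulators after infiltration.

    Infiltrated water first refills the stage-2 deficit, then the stage-1
    deficit; a large event clears both, returning the surface to stage-1
    drying at full potential (small events partially re-enable it).
    """
    take2 = min(infiltration, state.cum_evap_stage2)
    state.cum_evap_stage2 -= take2
    state.cum_evap_stage1 = max(0.0, state.cum_evap_stage1
                                - (infiltration - take2))
    if state.cum_evap_stage2 == 0:
        state.days_in_stage2 = 0


def drain(profile: SoilProfile, state: SoilWaterState) -> np.ndarray:
    """Cascade drainage; returns per-layer flux (mm) leaving each layer.

    Per layer, flux = swcon x (sw - dul) x thickness when sw > dul; water
    moves to the layer below (capped at its saturation); the bottom layer's
    flux leaves the profile.  Mutates state.
    """
    n = profile.n_layers
    flux = np.zeros(n)
    for i in range(n):
        excess = state.sw[i] - profile.dul[i]
        if excess <= 0:
            continue
        out = profile.swcon[i] * excess * profile.thickness[i]
        if i + 1 < n:
            room = (profile.sat[i + 1] - state.sw[i + 1]) * profile.thickness[i + 1]
            out = min(out, max(0.0, room))
            state.sw[i + 1] += out / profile.thickness[i + 1]
        state.sw[i] -= out / profile.thickness[i]
        flux[i] = out
    return flux


def _root_fractions(profile: SoilProfile, root_depth: float) -> np.ndarray:
    """Fraction of each layer's thickness explored by roots (pro-rated)."""
    top = np.concatenate([[0.0], profile.depth_bottom[:-1]])
    explored = np.clip(root_depth - top, 0.0, profile.thickness)
    return explored / profile.thickness


def root_water_uptake(state: SoilWaterState, profile: SoilProfile,
                      root_depth: float, demand: float
                      ) -> tuple[float, np.ndarray]:
    """kl-limited uptake from rooted layers; returns (supply mm, per-layer mm).

    Potential per layer = kl x (sw - ll15) x thickness x rooted fraction;
    extraction is scaled proportionally to meet min(demand, total potential).
    Mutates state.
    """
    if demand < 0:
        raise ValueError("demand must be >= 0")
    frac = _root_fractions(profile, root_depth)
    potential = profile.kl * np.maximum(0.0, state.sw - profile.ll15) \
        * profile.thickness * frac
    total = float(potential.sum())
    if total <= 0 or demand == 0:
        return 0.0, np.zeros(profile.n_layers)
    supply = min(demand, total)
    extraction = potential * (supply / total)
    state.sw -= extraction / profile.thickness
    return supply, extraction


def plant_available_water(state: SoilWaterState, profile: SoilProfile,
                          root_depth: float | None = None) -> float:
    """PAW (mm) over the rooted depth; partially-rooted layers pro-rated.

    ``root_depth`` None means the whole profile.
    """
    frac = (np.ones(profile.n_layers) if root_depth is None
            else _root_fractions(profile, root_depth))
    esw = np.maximum(0.0, state.sw - profile.ll15) * profile.thickness
    return float((esw * frac).sum())


def step_water_balance(state: SoilWaterState, profile: SoilProfile, rain: float,
                       eos: float, demand: float, root_depth: float,
                       runoff_coeff: float = 0.15, runoff_threshold: float = 20.0
                       ) -> tuple[SoilWaterState, WaterFlux]:
    """One day of the soil water balance; returns a new state and the fluxes.

    Order: rain partitioning -> cascading infiltration (overflow beyond a
    saturated profile joins runoff) -> drainage -> soil evaporation -> root
    uptake.  Raises if the returned fluxes fail mass conservation (bug trap).
    """
    s = state.copy()
    storage0 = s.storage(profile)
    cover = residue_cover(s.residue_mass)
    runoff, infiltration = partition_rain(rain, cover, runoff_coeff,
                                          runoff_threshold)
    # cascading fill to saturation
    remaining = infiltration
    for i in range(profile.n_layers):
        if remaining <= 0:
            break
        room = (profile.sat[i] - s.sw[i]) * profile.thickness[i]
        take = min(remaining, max(0.0, room))
        s.sw[i] += take / profile.thickness[i]
        remaining -= take
    if remaining > 0:  # profile saturated: excess ponds and runs off
        runoff += remaining
        infiltration -= remaining
    rewet_evaporation(s, infiltration)
    drainage = float(drain(profile, s)[-1]) if profile.n_layers else 0.0
    evap = soil_evaporation(s, profile, eos, cover)
    supply, _ = root_water_uptake(s, profile, root_depth, demand)
    delta = s.storage(profile) - storage0
    flux = WaterFlux(rain=rain, runoff=runoff, infiltration=infiltration,
                     drainage=drainage, soil_evap=evap, uptake=supply,
                     delta_storage=delta)
    if abs(delta - (infiltration - drainage - evap - supply)) > 1e-6:
        raise RuntimeError("water balance conservation violated: "
                           f"{delta} vs {infiltration - drainage - evap - supply}")
    return s, flux
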