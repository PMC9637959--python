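"""Thermal-time phenology: the lentil stage machine from sowing to maturity.

Development is driven purely by accumulated thermal time between cardinal
temperatures (base 0, optimum 30, maximum 40 degC for lentil).  Daily thermal
time uses eight 3-hourly temperatures interpolated on the diurnal cycle
between tmin and tmax (the classic APSIM cubic fractions), each mapped through
a piecewise-linear response with vertices (base, 0), (opt, opt-base), (max, 0)
and averaged.  This scheme matches a 1-minute sine-curve integration to well
under 0.5 degCd per day.

Germination is gated on seed-layer moisture and soil temperature, not thermal
time; sowing-to-emergence thermal time is shoot_lag + shoot_rate x depth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum

import numpy as np


class Stage(IntEnum):
    """The eleven lentil growth stages, in development order."""

    SOWING = 0
    GERMINATION = 1
    EMERGENCE = 2
    END_OF_JUVENILE = 3
    FLORAL_INITIATION = 4
    FLOWERING = 5
    START_GRAIN_FILL = 6
    END_GRAIN_FILL = 7
    MATURITY = 8
    HARVEST_RIPE = 9
    END_CROP = 10


@dataclass(frozen=True)
class ThermalResponse:
    """Cardinal temperatures (degC) for the thermal-time response."""

    base_temp: float = 0.0
    opt_temp: float = 30.0
    max_temp: float = 40.0

    def __post_init__(self) -> None:
        if not (self.base_temp < self.opt_temp < self.max_temp):
            raise ValueError("need base < opt < max cardinal temperatures")


# 3-hourly interpolation fractions of the diurnal range (period index 1..8)
_PERIODS = np.arange(1, 9)
_TEMP_FRACTIONS = (0.92105 + 0.1140 * _PERIODS
                   - 0.0703 * _PERIODS**2 + 0.0053 * _PERIODS**3)


def daily_thermal_time(tmax: float, tmin: float,
                       resp: ThermalResponse = ThermalResponse()) -> float:
    """Daily thermal time (degCd) from max/min temperature.

    Result lies in [0, opt - base]; 0 for days entirely outside [base, max].
    """
    if tmax < tmin:
        raise ValueError(f"tmax ({tmax}) < tmin ({tmin})")
    temps = tmin + _TEMP_FRACTIONS * (tmax - tmin)
    b, o, m = resp.base_temp, resp.opt_temp, resp.max_temp
    rising = np.clip(temps - b, 0.0, o - b)
    falling = np.clip((m - temps) / (m - o) * (o - b), 0.0, o - b)
    tt = np.where(temps <= o, rising, falling)
    tt = np.where((temps <= b) | (temps >= m), 0.0, tt)
    return float(tt.mean())


def emergence_threshold(depth: float, shoot_lag: float, shoot_rate: float) -> float:
    """Thermal time (degCd) from germination to emergence at a sowing depth (mm)."""
    if depth < 0 or shoot_lag < 0 or shoot_rate < 0:
        raise ValueError("depth, shoot_lag and shoot_rate must be non-negative")
    return shoot_lag + shoot_rate * depth


def germination_check(sw_seed_layer: float, ll15_seed_layer: float,
                      mean_soil_temp: float = 10.0,
                      base_temp: float = 0.0, eps: float = 0.002) -> bool:
    """Can the seed germinate today?

    Requires plant-extractable water in the seed layer (sw - ll15 > eps
    volumetric) and a 3-day mean soil temperature above the base temperature.
    """
    return (sw_seed_layer - ll15_seed_layer) > eps and mean_soil_temp > base_temp


@dataclass(frozen=True)
class CultivarCoefficients:
    """The per-variety parameter set: phenology durations (degCd), emergence
    shoot parameters, node appearance, leaf size anchors, RUE and HI rate.

    ``node_app_rate`` is degCd per mainstem node; ``leaf_size_node8`` /
    ``leaf_size_node14`` anchor individual leaf size (mm2) at the 8th node
    (end of juvenile) and 14th node (floral initiation).  ``rue`` is g
    aboveground biomass per MJ of intercepted *solar* radiation (the
    convention used when regressing biomass on radiation x fiPAR).
    """

    name: str
    shoot_lag: float = 60.8              # degCd
    shoot_rate: float = 2.42             # degCd/mm sowing depth
    tt_emerg_to_endjuv: float = 600.0
    tt_endjuv_to_init: float = 200.0
    tt_init_to_flower: float = 150.0
    tt_flower_to_start_grain: float = 220.0
    tt_start_to_end_grain: float = 600.0
    tt_end_grain_to_maturity: float = 100.0
    node_app_rate: float = 59.0          # degCd/node
    leaf_size_node8: float = 180.0       # mm2/leaf at 8th node
    leaf_size_node14: float = 260.0      # mm2/leaf at 14th node
    rue: float = 1.10                    # g/MJ (solar)
    hi_rate: float = 0.0110              # fraction/day during grain fill
    hi_max: float = 0.60
    initial_node_offset: float = 0.0     # nodes present at emergence
    thermal: ThermalResponse = field(default_factory=ThermalResponse)

    def __post_init__(self) -> None:
        for f_ in ("tt_emerg_to_endjuv", "tt_endjuv_to_init", "tt_init_to_flower",
                   "tt_flower_to_start_grain", "tt_start_to_end_grain",
                   "tt_end_grain_to_maturity"):
            if getattr(self, f_) <= 0:
                raise ValueError(f"{f_} must be > 0")
        if not 0 < self.hi_rate < 0.05:
            raise ValueError("hi_rate must lie in (0, 0.05) /day")
        if not 0 < self.hi_max <= 0.6:
            raise ValueError("hi_max must lie in (0, 0.6]")
        if self.rue <= 0 or self.node_app_rate <= 0:
            raise ValueError("rue and node_app_rate must be > 0")

    def leaf_size_at(self, node: float) -> float:
        """Individual leaf size (mm2) at a (real-valued) node position.

        Linear between the 8th- and 14th-node anchors, constant outside.
        """
        return float(np.interp(node, [8.0, 14.0],
                               [self.leaf_size_node8, self.leaf_size_node14]))

    def phase_duration(self, stage: Stage) -> float | None:
        """Thermal-time target for leaving ``stage`` (None for non-TT stages)."""
        return {
            Stage.EMERGENCE: self.tt_emerg_to_endjuv,
            Stage.END_OF_JUVENILE: self.tt_endjuv_to_init,
            Stage.FLORAL_INITIATION: self.tt_init_to_flower,
            Stage.FLOWERING: self.tt_flower_to_start_grain,
            Stage.START_GRAIN_FILL: self.tt_start_to_end_grain,
            Stage.END_GRAIN_FILL: self.tt_end_grain_to_maturity,
        }.get(stage)


@dataclass(frozen=True)
class PhenologyState:
    """Current stage plus thermal-time bookkeeping (all degCd)."""

    stage: Stage = Stage.SOWING
    tt_in_stage: float = 0.0
    tt_since_emergence: float = 0.0
    node_number: float = 0.0


def update_nodes(tt_since_emergence: float, node_app_rate,
                 initial_offset: float = 0.0) -> float:
    """Mainstem node number after a given thermal time since emergence.

    ``node_app_rate`` is degCd/node, either a scalar or a lookup given as a
    sequence of (node_number, rate) breakpoints: the rate holding from that
    node onward (piecewise constant).  Returns the real-valued node number;
    callers needing an integer count floor it.
    """
    if tt_since_emergence < 0:
        raise ValueError("tt_since_emergence must be >= 0")
    if np.isscalar(node_app_rate):
        if node_app_rate <= 0:
            raise ValueError("node_app_rate must be > 0")
        return initial_offset + tt_since_emergence / float(node_app_rate)
    nodes_bp = [float(n) for n, _ in node_app_rate]
    rates = [float(r) for _, r in node_app_rate]
    if any(r <= 0 for r in rates):
        raise ValueError("node_app_rate lookup rates must be > 0")
    node = nodes_bp[0]
    tt = tt_since_emergence
    for i, rate in enumerate(rates):
        nxt = nodes_bp[i + 1] if i + 1 < len(nodes_bp) else np.inf
        tt_segment = (nxt - node) * rate
        if tt < tt_segment:
            return initial_offset + node + tt / rate
        tt -= tt_segment
        node = nxt
    return initial_offset + node  # unreachable: last segment is unbounded


def advance_phenology_detailed(state: PhenologyState, tt_today: float,
                               cultivar: CultivarCoefficients,
                               sowing_depth: float
                               ) -> tuple[PhenologyState, list]:
    """Advance the stage machine by one day's thermal time.

    Adds ``tt_today`` to the current stage accumulator and transitions
    (carrying surplus degCd across the boundary) whenever the stage target is
    met.  Germination->emergence targets shoot_lag + shoot_rate x depth; later
    stages use the cultivar phase durations.  Sowing (pre-germination) and
    post-maturity stages do not accumulate.

    Returns the new state plus the day's crossings as (stage entered,
    fraction of the day's thermal time consumed at the crossing) — the
    sub-daily transition times on the thermal clock.
    """
    if tt_today < 0:
        raise ValueError("tt_today must be >= 0")
    stage = state.stage
    if stage == Stage.SOWING or stage >= Stage.MATURITY:
        return state, []
    tt_in_stage = state.tt_in_stage + tt_today
    tt_since_emerg = state.tt_since_emergence
    if stage >= Stage.EMERGENCE:
        tt_since_emerg += tt_today
    crossings = []
    consumed = -state.tt_in_stage  # today's degCd spent when a target is hit
    while stage < Stage.MATURITY:
        if stage == Stage.GERMINATION:
            target = emergence_threshold(sowing_depth, cultivar.shoot_lag,
                                         cultivar.shoot_rate)
        else:
            target = cultivar.phase_duration(stage)
        if target is None or tt_in_stage < target:
            break
        surplus = tt_in_stage - target
        consumed += target
        fraction = consumed / tt_today if tt_today > 0 else 1.0
        if stage == Stage.GERMINATION:
            # thermal time since emergence starts counting at the transition
            tt_since_emerg += surplus
        stage = Stage(stage + 1)
        crossings.append((stage, min(max(fraction, 0.0), 1.0)))
        tt_in_stage = surplus
    node = state.node_number
    if Stage.EMERGENCE <= stage < Stage.FLOWERING:
        # mainstem node appearance ceases once flowering is reached
        node = update_nodes(tt_since_emerg, cultivar.node_app_rate,
                            cultivar.initial_node_offset)
    return PhenologyState(stage, tt_in_stage, tt_since_emerg, node), crossings


def advance_phenology(state: PhenologyState, tt_today: float,
                      cultivar: CultivarCoefficients,
                      sowing_depth: float) -> PhenologyState:
    """As :func:`advance_phenology_detailed`, returning only the new state."""
    new_state, _ = advance_phenology_detailed(state, tt_today, cultivar,
                                              sowing_depth)
    return new_state


def germinate(state: PhenologyState) -> PhenologyState:
    """Move a sown (ungerminated) crop to the germination stage."""
    if state.stage != Stage.SOWING:
        raise ValueError("germinate() only applies to the sowing stage")
    return replace(state, stage=Stage.GERMINATION, tt_in_stage=0.0)
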