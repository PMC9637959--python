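# Methods

This note documents the model, its parameters and the design choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Scope and intent

`lentilsim` is a minimal daily-timestep lentil simulator plus the analysis
chain around it: coefficient estimation from trial observations, skill
metrics, and a genotype × environment × management (G×E×M) factorial with
variance-based sensitivity indices. It is built to study *structure* —
which factors drive yield and plant-available water in which rainfall
environments, and how ideotypes and agronomy interact under terminal
drought — on synthetic climates with known ground truth. It is not a
calibrated replacement for a full cropping-systems model: nitrogen,
frost/heat damage, pests, photoperiod and senescence are all out of scope.

## Phenology

Thermal time uses cardinal temperatures 0/30/40 °C (base/optimum/maximum).
Sub-daily temperatures are the eight classic 3-hourly interpolation
fractions of the diurnal range (`0.92105 + 0.1140n − 0.0703n² + 0.0053n³`,
n = 1…8); each is mapped through the piecewise-linear response
(0,0)–(30,30)–(40,0) and the eight responses averaged. A brute-force
1-minute sine integration agrees within 0.5 °Cd/day over the relevant
temperature range (property-tested); the cubic-fraction scheme was chosen
over literal 3-hour sine means because only it meets that oracle band.

Stages run sowing → germination → emergence → end of juvenile (≡ 8th node)
→ floral initiation (≡ 14th node) → flowering → start/end of grain fill →
maturity. Germination needs extractable water in the seed layer
(sw − ll15 > 0.002 v/v) and a 3-day mean air temperature above base; no
thermal time accrues while the seed waits. Germination → emergence consumes
`shoot_lag + shoot_rate × sowing depth` °Cd; all later phases are fixed
per-cultivar °Cd with **no photoperiod or vernalization modifiers** —
durations are treated as cultivar constants, which is how they are
parameterized from single-site trials. Surplus °Cd carries across a
transition on the same day, so phase totals are conserved; the simulator
also records each transition *time* at sub-daily resolution on the thermal
clock (the fraction of the day's °Cd consumed at the crossing). Noiseless
synthetic trials report these exact times, which is what lets the
phase-duration estimator recover generating values to machine precision;
with any observation noise, records collapse to calendar days and recovery
is only guaranteed to within one day's thermal time.

Mainstem nodes appear every `node_app_rate` °Cd after emergence (a scalar,
or a piecewise lookup of rate vs node number) and cease at flowering.
An optional `initial_node_offset` (default 0) covers counting conventions
that start at 1 at emergence.

## Canopy, biomass, yield

Each new node adds leaf area: individual leaf size (mm²) interpolated
linearly between anchors at the 8th and 14th node and constant outside,
times `leaves_per_node` (default 4 — an effective multiplicity representing
the leaf area contributed by concurrently developing branches, chosen so a
120 plants/m² canopy approaches LAI ≈ 2 by flowering), times plant density.
There is no senescence; the season ends at maturity.

Interception is Beer's law with extinction coefficient k = 0.5 at the
190 mm reference row spacing; wider rows intercept less at equal LAI
(k-multiplier 1.0 → 0.85 linearly from 190 → 380 mm). Wide rows also shade
the soil surface less effectively *per unit fiPAR* (shading factor
1.0 → 0.75 over the same range) because the inter-row gap stays
sun-exposed; this geometric asymmetry is what gives narrow rows their small
water-economy advantage in dry seasons.

Biomass: ΔW = radn × fiPAR × RUE × stress, with RUE in g/MJ of intercepted
*solar* radiation (the estimation convention: biomass regressed on
cumulative radn × fiPAR). Transpiration demand is
ΔW_pot × VPD / (TE × 1000) with TE = 0.005 kPa and
VPD = 0.75 × (svp(tmax) − svp(tmin)); stress = min(1, supply/demand)
applies to biomass only, never to phenology (a deliberate simplification:
drought-accelerated development is not modelled). Roots extend 20 mm/day
from emergence to the start of grain fill, capped at the profile depth.

Harvest index rises linearly at the cultivar HI rate from the start of
grain fill through the day maturity is reached, capped at `hi_max`
(0.6 for the shipped panel), and yield = HI × biomass at all times. The cap
is what makes large HI-rate increments non-additive: a ×1.4 ideotype
saturates the cap and realises much less than +40% yield.

## Soil water

A layered bucket (defaults mirror a 0–130 cm profile in 7 layers).
Daily order of operations: rain partitioning → cascading infiltration to
saturation (overflow joins runoff) → drainage → soil evaporation → root
uptake; the flux object is checked for closure to 10⁻⁶ mm every day.

* Runoff: coeff 0.15 × (1 − residue cover) × rain above a 20 mm/day
  threshold (flat paddocks; set the coefficient to 0 to disable).
* Drainage: flux = swcon × (sw − dul) × thickness cascading downward,
  swcon default 0.3/day; no unsaturated redistribution.
* Soil evaporation: potential is an equilibrium-evaporation proxy
  eo = 1.1 × radn × (4.88·10⁻³ − 4.37·10⁻³ × albedo) × (0.6 tmax + 0.4 tmin + 29),
  shaded by canopy (× (1 − fiPAR × row-shading)) and reduced by residue
  (× (1 − 0.8 × cover), cover = 1 − exp(−0.4 × t/ha) for wheat stubble).
  Two-stage drying: stage 1 at potential until U = 6 mm accumulate, then
  stage 2 on cona × (√t − √(t−1)) with cona = 3.5 mm/day^0.5, where t is
  carried implicitly as (Σstage-2 / cona)². Infiltration *subtracts from*
  the stage-2 then stage-1 accumulators, so small rain events re-enable
  first-stage drying and a large event resets it entirely. This
  subtraction convention (rather than a fixed >10 mm reset) matters:
  winter rainfall here arrives mostly as small events, and it is the
  repeated re-evaporation of those events from bare soil — prevented by
  stubble — that makes residue the dominant factor in dry environments.
  The top layer never dries below half its ll15 (air-dry floor).
* Uptake: per rooted layer kl × (sw − ll15) × thickness (kl 0.06 in the
  top layer decaying ×0.9 per layer), pro-rated for the partially rooted
  layer, scaled to min(demand, total potential).

## Synthetic data

The generators define the study conditions; they emulate south-eastern
Australian winter-dominant semi-arid climate, not any particular station.

* **Weather.** Temperature and radiation follow southern-hemisphere
  seasonal sinusoids (warmest mid-January) plus bounded Gaussian noise with
  tmax ≥ tmin enforced by construction. Rainfall is a first-order wet/dry
  occurrence chain (stationary wet probability 0.35 in April–October, 0.12
  otherwise; wet-after-wet 0.55/0.35) with gamma amounts (shape 0.75)
  scaled so the annual mean hits the class target with 70% of rain in
  April–October. Classes: low 250 mm, medium 375 mm, high 550 mm/year.
  One seed is split into independent streams via
  `numpy.random.SeedSequence.spawn`.
* **Soils.** Plausible clay profiles whose PAWC hits a target within
  0.5 mm; dul/ll15 rise gently with depth and capacity tapers downward.
  `initial_fill` defaults to 0.25 of the available range — a profile only
  partly recharged after a dry summer fallow, which is the typical sowing
  condition in these environments and the setting under which the drought
  analysis is meaningful.
* **Trials.** `generate_trial` forward-simulates (well-watered by default,
  matching parameterization trials "under optimum field conditions") and
  samples the field protocol: six harvest dates from the start of grain
  fill to maturity, each cut in three replicate plots; fortnightly
  ceptometer pairs from emergence; weekly node counts to flowering; stage
  dates. Noise: additive Gaussian days on stage dates, multiplicative
  log-normal on biomass, additive on HI and node counts, multiplicative on
  transmitted PAR — defaults are conventions (the source trials publish no
  variance structure). All-zero noise yields observations exactly
  consistent with the generating coefficients.

What passing the recovery tests shows: the estimators invert the generator
faithfully under its noise model. What it does not show: robustness to real
field pathologies (missing harvests, instrument drift, spatial trend,
lodging), none of which the generator emulates.

## Estimators

All are OLS with free intercept ("slope of the line" procedures; whether
the source regressions forced zero intercepts is unknown, so the free
intercept is recorded in the estimate metadata). fiPAR between fortnightly
readings is linearly interpolated in time, ramping from 0 at emergence to
the first reading and held after the last. The HI-line x-intercept is
reported as an estimated start of grain fill, but stage-date observations
take precedence for phenology when both exist. The HI-rate estimate carries
a plausibility flag against the published lentil band 0.0090–0.0139 day⁻¹.

## Skill metrics

RMSE, mean-normalised RMSE, Pearson r, Nash–Sutcliffe efficiency,
Willmott's d and Lin's CCC, all with population (1/n) moments so the
perfect-agreement identities are exact (the variance convention is not
otherwise pinned down). Qualitative bands: d and NSE in four classes with
*inclusive* lower boundaries (d ≤ 0.75 is unsatisfactory); RMSE flagged
good at ≤ 5 days (flowering), ≤ 0.5 t/ha (yield), ≤ 1.5 t/ha (biomass).
Constant observed series make r/NSE/CCC undefined; they are reported as
NaN with a reason rather than raising.

## Scenario engine and sensitivity

Default factorial: five sowing dates (28 Apr, 12 May, 26 May, 7 Jun,
23 Jun) × stubble 0/6 t/ha × rows 190/380 mm × genotypes, over every
site-year. Ideotypes multiply leaf size, RUE and HI rate *jointly* by
1.1–1.4 over a baseline (per-trait mode available via `joint=False`);
phenology is never modified. Stubble is reinitialized each season (no
carry-over). Failed seasons (weather exhausted before maturity) become
flagged rows with missing yield, never dropped.

Environment cells (site-years) are classified into rainfall terciles of
mean growing-season rainfall. Drought impact is
(1 − ȳ_group / ȳ_high) × 100 with the reference either each genotype ×
management's own high-rainfall mean (default) or a fixed baseline strategy
via `reference_filter` — the latter is the right convention for asking how
much a strategy mitigates drought relative to current practice.

ME and TE are computed by group-by means with population variances,
count-weighted; on balanced full factorials they equal the brute-force
enumeration (oracle-tested to 10⁻¹²), additive responses give ΣME = 1 and
TE = ME, and TE ≥ ME. Unbalanced tables produce a warning and weighted
estimates.

## Problem sizes

The directional G×E×M checks in the test suite run one synthetic site per
rainfall class × 8 years × 3 sowing dates × 2 stubble × 2 spacings × 5
genotype levels (1,440 season simulations) — large enough for the variance
decomposition to stabilise while keeping the whole suite quick on a single
CPU. The full 15-site × 50-year design of the original study (750
environment cells; 150,000 rows at the default factor levels) is supported
by the same code path and is what `design_cells(15, 50)` enumerates.

## Known limitations

* Water stress does not feed back on phenology or leaf area (no
  drought-accelerated maturity, no expansion stress), so simulated dry
  seasons understate phenological escape.
* No nitrogen, frost/heat, pests, lodging or senescence; yields in
  favourable synthetic seasons sit at the optimistic end of the plausible
  range.
* The row-spacing mechanism (k-multiplier + soil-shading asymmetry) is a
  parsimonious stand-in for real row-geometry radiative transfer; its
  constants are pinned only by directional behaviour.
* The shipped cultivar panel is representative (built from published
  in-text ranges), not a measured per-variety dataset; conclusions should
  be drawn from relative, not absolute, numbers.
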