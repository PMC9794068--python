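# Model description and methods

This note documents the models implemented in `carabsim`, their
assumptions, the parameters that matter, and the design choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Scope and intent

The package implements a policy-oriented simulation experiment at desk
scale: a spatially explicit, super-individual population model of the
carabid beetle *Bembidion lampros* living in dynamic agricultural
landscapes, exposed to insecticide application scenarios. Experiments of
this kind are usually run on real national topographic and land-parcel
data; here the landscapes are synthetic but emulate the same statistical
structure
(field/farm organisation, rotations, management events, weather), so
that the *mechanisms* — exposure mathematics, population processes,
endpoint extraction, regression analysis — can be exercised and tested
end to end with full reproducibility.

## Synthetic landscape

The landscape is a categorical raster with one element type per cell
(arable field, managed grassland, herbaceous semi-natural, woodland,
water, built-up, field margin, crop-free buffer, other) and a parallel
field-identity band. Cell (0,0) sits at the lower-left corner; cell
extents are half-open; all distances are metres.

Fields are axis-aligned rectangles produced by seeded recursive binary
splits (35–65 % positions) of the extent; this keeps perimeter and area
computation exact, and the heterogeneity metrics depend only on areas
and edges, not on parcel-shape realism. Blocks are allocated to
herbaceous patches, woodland and built-up area until their area budgets
are met; the rest become parcels. A seeded fraction of parcels
(default 0.6) keeps a 1-cell herbaceous verge ring — the grassy field
boundary that is this species' main overwintering habitat; without
distributed boundary habitat, overwintering concentrates in a few large
patches and winter occupancy decouples from local summer survival, which
is not how field-boundary-hibernating carabids work. Water ditches are
1-cell lines along parcel edges (so parcels stay connected), and every
cropped cell 4-adjacent to water becomes a 1-m crop-free buffer, reset
to fallow-with-regrowing-grass semantics each year and never sprayed.

Parcels are grouped into farms of ~5 fields by spatial adjacency. Farm
types default to an intensive mixed-arable mix (10 % animal grazing,
30 % arable, 25 % arable-vegetable, 15 % starch potato, 10 % flower,
10 % other): the farming context that insecticide-mitigation policy
targets (potato, vegetable and bulb growing), and the context in which
beetle populations respond most clearly to toxicity changes. Fields of
animal-grazing farms are managed grassland.

The grassy-margin mitigation carves an inner ring (default 4 m wide)
from the cropped area of a seeded random half of parcels, sampled
uniformly without replacement among parcels large enough to keep a
non-empty interior; margins keep their parcel's field id but are never
cultivated or sprayed. Re-applying the operation with the same fraction
is a no-op (already-margined parcels count toward the quota), and buffer
creation is likewise idempotent.

**Metrics.** Landscape diversity is Shannon's index over six aggregate
categories (arable incl. managed grassland; herbaceous semi-natural
incl. margins and buffers; woodland; built-up; water; other). The
landscape shape index follows the raster convention LSI = 0.25·E/√A
with cell-edge counting *including the landscape boundary* — whether
the boundary edge is included is not standardized, so one convention is
fixed and documented; LSI = 1 for a single square patch. Farming
diversity is Shannon's index over farm types weighted by field area;
boundary density is Σ parcel perimeter / Σ cultivated area. Generator
presets at study scale produce metric values in the ranges typical of
10 × 10 km mixed agricultural landscapes; this is logged, not asserted,
since the desk-scale extent compresses some metrics (notably LSI, which
scales with √A).

## Farming calendar

Each farm type has a 100-entry crop rotation (one entry per 1 % of
area). Every field starts at a uniform random rotation index and
advances by one entry at each year end, so over 100 years each field
grows every entry exactly once and instantaneous crop shares match entry
multiplicities on average. Catch crops can be represented as ordinary
rotation entries.

Management plans are ordered event lists with day-of-year windows and
execution probabilities. Scheduling draws each firing event's day
uniformly in its window; plough/harrow/sow/harvest may never precede an
earlier ordered activity (an event whose window closes under that
constraint is dropped and logged); sprays are pushed past days with
precipitation above 2 mm, at most 10 days beyond the window end. The
packaged default plans (cereals, root crops, vegetables, flower bulbs,
grassland) are clearly-labelled configurable defaults — no time window
or probability was available from any measured source. Insecticide
applications are confined to the intensively treated crops (potatoes,
vegetables, tulips; 2–3 events per season at probabilities 0.5–0.9);
fungicides and herbicides are scheduled but deposit nothing and have no
direct effect on the beetles.

The calendar uses 365-day years (no leap days), so day-of-year 59 is
always March 1.

**Weather** is synthesized, not downloaded: a sinusoidal annual
temperature cycle (mean 10 °C, amplitude 7 °C, coldest mid-January)
plus AR(1) daily noise (sd 2.5 °C, ρ = 0.7), precipitation from a
two-state Markov chain (P(wet|wet) = 0.65, P(wet|dry) = 0.25) with
gamma wet-day amounts, and AR(1) wind. Only the seasonal structure
matters for the development, decay and phenology processes; the
parameters emulate a temperate-maritime lowland climate. One weather
series per experiment is shared by all scenarios and replicates.

A simplified vegetation state (degree-day saturating height curve,
reset at sowing/harvest/cut) is provided for completeness; habitat
quality in the beetle model is driven by element type, not by daily
vegetation height.

## Exposure and effects model

All concentrations are in trigger-threshold units (toxic units): 1.0 is
the environmental concentration above which exposure mortality applies.

* **Lethality classes.** LR90/LR50/LR25 = 90/50/25 % of exposed beetles
  dying over a 7-day field test. The daily probability solves
  (1 − m) = (1 − p)^d, giving p = 0.28, 0.09, 0.04 (2 d.p.) at d = 7.
  The effect duration defaults to 7 days for every class and is
  configurable.
* **Degradation.** First-order decay with half-life DT50 at the 20 °C
  reference, scaled by DT50(T) = DT50(20)·exp(ln 2.58 · (20 − T)/10);
  each day every cell is multiplied by 0.5^(1/DT50(T_today)).
* **Treatment rate.** rate = 1/0.5^(d/DT50): the deposit that decays to
  exactly the trigger after the d-day effect period at 20 °C — 41.78
  toxic units at DT50 = 1.3 d. Evaluated at DT50 = 25 d the same
  formula gives 1.21 (2 d.p.), 0.01 below the conventionally quoted
  1.22 for that product class; the formula, which is exactly consistent
  with the decay model (a property test asserts the round trip to
  machine precision), is authoritative here.
* **Spray drift.** %drift = A·dist^B with A = 2.7705, B = −0.9787
  (downward-sprayed field crops), zero beyond 12 m. Drift-reducing
  technology scales the whole curve by (1 − reduction), preserving the
  exponent — the stated percentage semantics of 50 %/90 % reduction.
  Drift distance is the Euclidean distance from the receiving cell
  centre to the nearest sprayed cell centre, so the first off-field
  ring at 1-m resolution sits at 1 m, the lower edge of the curve's
  calibrated domain. Wind direction is not modelled; drift deposits
  isotropically.
* **Application.** Spraying a field adds the full treatment rate to its
  cropped cells (margins and buffers excluded) and rate·%drift/100 to
  every other cell within 12 m. Exposure mortality applies to
  surface-active adults only: a beetle in a cell at or above the
  trigger dies with probability p — no dose–response. Juveniles are
  beneath the soil surface and exempt from spray mortality (but subject
  to soil-cultivation mortality); hibernating adults are in untreated
  refuge vegetation outside the spray season and are not exposed.
  A super-individual dies or survives as a unit, matching the agent
  granularity.

## Beetle population model

Agents are super-individuals (100 beetles each; configurable) in four
stages: egg, larva, pupa, adult female. Males are not followed (all
females assumed fertilized); winged dispersal morphs (<10 % of real
populations) and prey dynamics are not modelled. The population is a
structure of arrays and all daily processes are vectorized.

**Development.** Immatures accumulate degree-days above a base
temperature (default 3 °C); stage requirements default to 90 (egg),
220 (larva), 130 (pupa) °C·days with the counter reset at each
transition, and daily background mortality 0.03/0.04/0.02. These —
like fecundity (Poisson mean 1.5 egg super-individuals per female-day
in the day-135–196 breeding window), farm-operation mortalities
(0.10–0.50 by operation and stage group), overwinter mortality (0.40 in
boundary/semi-natural habitat, 0.95 outside, 0.90 for late juveniles)
and the adult daily background rate (0.004) — are configurable,
literature-magnitude defaults: none are measured values, and none are
acceptance-relevant.

**Movement** (adults only, ≤ 14 m/day) has three modes. Foraging: a
uniform random heading and step length, re-drawn up to 3 times if the
destination is unsuitable; sub-optimal habitat (woodland, bare "other")
accepted with probability 0.1; water and built-up never. Autumn
migration: from October 1 each forager starts, with daily probability
0.08, a biased walk (bias weight 0.9) toward the nearest overwintering
cell (verge, margin, buffer, herbaceous patch), capped so the target is
not overshot; arrival switches to hibernation. Spring dispersal: when
the 5-day running mean temperature reaches 7 °C, hibernators walk
biased toward the nearest cropped cell and resume foraging there. The
autumn start probability and spring trigger are not published anywhere;
both are configurable with these documented defaults.

**Density dependence.** Within the 3 m × 3 m square around any beetle
at most 2 adults and 2 larvae may remain; surplus agents are removed at
random. Enforcement is iterative random thinning (each member of an
over-full window removed with probability excess/occupancy, with a
forced single removal per stuck iteration), which terminates with the
predicate holding exactly; a brute-force window scan verifies this in
the tests. At raster resolutions coarser than 1 m the window is the
smallest odd cell count covering ≥ 3 m (3 × 3 cells at 2-m cells), i.e.
the cap is never more permissive than the 1-m rule. The cap counts
agents (super-individuals), not represented beetles. Eggs additionally
obey a per-cell cap (default 6) — a numerical guard standing in for egg
cannibalism; since larvae are capped anyway, surplus eggs would be
removed a stage later, and the guard bounds agent-array growth.

**Daily sub-step order** (fixed; the underlying biology is silent on
within-day ordering): (1) farm operations and spray applications,
(2) exposure decay then exposure mortality, (3) development and
background mortality, (4) reproduction, (5) seasonal mode switches and
movement, (6) density dependence, with the once-per-winter mortality on
day 335. Sprays precede movement because at spraying time the
population is in the field; the chosen order makes that exposure
effective. An agent-count balance (start + births − deaths − removals =
end) is asserted after every step.

## Scenarios, replication and endpoints

The scenario matrix crosses lethality class (LR90/LR50/LR25),
spray-drift reduction (50 % everywhere; 90 % tested for LR90 only),
margins on/off, and two persistence classes (DT50 = 1.3 and 25 days):
16 scenarios, with LR90 + 50 % drift reduction + no margins as the
worst-case baseline per persistence class.

Replicates share the landscape geometry and weather but redraw beetle
placement, rotation phases and event-timing draws. A replicate's RNG
stream is keyed on (master seed, replicate) and shared across scenarios:
a replicate is a set of initial conditions, so scenario contrasts at
equal replicate are paired (common random numbers). This sharpens
contrasts at desk-scale replicate counts — a treatment with no real
effect produces (near-)identical trajectories instead of independent
noise — and keeps every output independent of scenario execution order.
Initial adults (2000 super-individuals per km², area-scaled) are placed
uniformly over suitable habitat, hibernating (runs start January 1).

Endpoints are extracted on day 59 of each year: overall density (adult
females per ha over the whole landscape), Occupancy (proportion of
50 m × 50 m aggregation cells holding ≥ 100 adult females — at least
one super-individual at the default factor) and Abundance (mean female
density inside occupied cells). The sometimes-quoted "50 m²" cell is
read as a 50 m × 50 m cell, the only reading under which a 100-beetle
threshold is attainable; partial boundary cells are dropped. Years are
averaged within replicate, then means and coefficients of variation
(sample-sd, ddof = 1) are taken across replicate means; scenario effects
are percentage changes versus the matching-persistence baseline (AOR
deltas). A zero baseline value leaves the delta undefined (reported
missing).

## Regression stage

Heterogeneity metrics are pre-filtered: while any pair's Pearson |r|
exceeds 0.7, the member of the worst pair with the higher mean absolute
correlation to the remaining columns is dropped (ties alphabetically —
the later name goes). The removal order is one defensible fixed rule;
alternatives exist and would retain different survivors on strongly
clustered predictors. Models are ordinary least squares fitted by
backward-stepwise AIC (drop the term whose removal lowers AIC most,
stop when none does; Gaussian-likelihood AIC, whose additive constant
cancels in comparisons), reporting adjusted R², coefficient p-values
and the model F-test p-value. The selected model's AIC never exceeds
the full model's (asserted). Runs with fewer than 30 observations are
flagged small-sample and warn — at n = 10 landscapes the stage runs but
selection is unstable by construction.

## Desk scale, problem sizes and what the tests show

The default profile is 1 km × 1 km at 2-m cells, ~100 fields, 5 years,
3 replicates — the scale at which the full scenario experiment runs on
a single CPU in minutes. The study-scale profile (10 × 10 km at 1 m,
30 years, 10 replicates, 2000+ fields) is supported but long-running.
Directional scenario findings at desk scale (lower toxicity and margins
help, extra drift reduction is within replicate noise, combined
measures beat single ones on occupancy) are the transferable result;
absolute densities and the headline effect magnitudes depend on the
real landscapes' structure and are not reproduced by synthetic
geometry. The synthetic generator emulates field/farm organisation and
area budgets but not parcel-shape realism, soil-type-driven management
switching, grazing disturbance, or real product dosages — passing tests
therefore validate mechanism and implementation, not site-specific
predictions.

Numerical conventions collected in one place: trigger threshold ≡ 1
toxic unit; exposure arrays float64 with decay skipped when the grid
maximum is below 1e-9; drift distances by Euclidean distance transform;
movement in continuous metre coordinates with cell indices derived by
flooring; Poisson egg clutches; all randomness through numpy Generators
derived from named SeedSequence keys (every run is bit-reproducible
from the master seed).
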