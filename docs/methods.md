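# Methods

`scenplan` implements a scenario-based systematic conservation-planning
workflow: simulate plausible land-cover futures, map each species'
available habitat under every future, select priority planning units with
a simulated-annealing optimiser, build conservation-area portfolios under
three strategies, and score their robustness as the number of species
whose representation targets are met in each scenario.

## The planning model

**Planning units and costs.** The landscape raster is tiled into square
planning units (PUs), 1 km² by default. PU area is the cost surrogate, so
minimising cost minimises the area needed to meet targets. PUs with a
protected-area share above 50% are locked into every solution (already
protected, zero cost); PUs more than 50% built-up are locked out. Lock
status is evaluated on each land-cover state: a scenario's selection
problem uses that scenario's built shares, while portfolio construction
and evaluation use present-day status, because the reserve system is
established today.

**Representation targets.** A species with present-day available habitat
A (km²) receives a target of 100% of A when A < 100 km², 10% when
A > 1,000 km², and otherwise the linear interpolation in percent space,
`percent = 100 − 0.1 (A − 100)`, through (100 km², 100%) and
(1,000 km², 10%). The wording of that rule admits a second reading —
interpolating the target *area*, constant at 100 km² on the intermediate
range — which is exposed as `mode="area"`; both agree at the thresholds,
and percent space is the default. For each scenario the target is capped
at the habitat remaining in that scenario, so it stays achievable.

**Objective.** A candidate reserve (set of selected PUs) is scored as

    cost(selected available PUs)
    + BLM × boundary length
    + Σ_s SPF_s × max(0, (target_s − held_s) / target_s)

with BLM = 0.001. Boundary length counts edges between selected and
unselected PUs plus the study-area perimeter of selected available PUs;
locked-in PUs contribute habitat but neither cost nor perimeter penalty.
The shortfall penalty is normalised by the target so species penalty
factors (SPFs) are dimensionless and comparable across species; the
original MARXAN cost-to-fix penalty heuristic is not reproduced — the
analysis depends only on the three-component structure.

**Optimiser.** Simulated annealing over single-PU flips on available PUs:
improving moves always accepted, worsening moves with probability
exp(−Δ/T); geometric cooling (factor 0.97 every iterations/100 moves);
initial temperature, unless given, is 10× the SD of objective deltas over
100 random flips from the random start; a greedy descent (accept only
improving flips until none remains) finishes each run. The flip loop is
numba-compiled; runs are deterministic given their seed. An exhaustive
enumerator (≤ 20 available PUs, ties broken by cardinality then
lexicographic PU ids) is the optimality oracle in tests: on 200 random
small problems the annealer at 20,000 iterations attains the optimum in
well over 95% of cases and, by construction (its objective is recomputed
with the same arithmetic the enumerator uses), can never appear better.

**Selection frequency and SPF calibration.** Selection frequency is the
fraction of independent restarts whose best solution contains a PU.
SPFs are calibrated iteratively: starting at 1 for every species, each
round runs a batch of restarts and doubles the SPF of every species whose
target is met in ≤ 90% of restart solutions, stopping when all species
exceed 90% (or warning after `max_rounds`). Calibration rounds use
shorter anneals (5,000 iterations, 10 restarts) than the production
frequency run (100 restarts × 20,000 iterations by default; the
study-scale preset of 1,000 × 1,000,000 is available as `PAPER_PRESET`).

**Portfolios.** Three strategies are compared at a common natural-area
budget:

* *current* — PUs whose present-day selection frequency exceeds 0.9
  (strict), plus locked-in PUs. Its purchased natural area (natural-cover
  area of selected minus locked-in PUs on the present-day map) defines
  the budget.
* *scenario subsets* — for each value of the three scenario factors
  (climate regime, urban policy, development rate), PUs are ranked over
  that factor's scenarios by coefficient of variation of selection
  frequency (ascending; population SD over the subset's scenarios), ties
  by mean frequency (descending) then PU id; the ranking is walked,
  skipping locked-out and never-selected (mean 0, CV undefined) PUs,
  accumulating present-day natural cover until the budget is reached
  (the crossing PU is included).
* *all-scenarios* — the same CV ranking over the full 12-scenario set.

Locked-in PUs belong to every portfolio and consume no budget; for the
nine-portfolio equal-area invariant to be well defined, the stored
`natural_area_km2` is always the purchased natural area.

**Evaluation.** A species is *covered* by a portfolio in a scenario iff
its scenario-capped target is positive and the suitable area inside the
portfolio's PUs under that scenario's land cover is ≥ the target
(inclusive); a species whose habitat vanished entirely (capped target 0)
counts as not covered for every portfolio. Performance per portfolio per
scenario group is the mean and population SD of covered counts. Spatial
agreement between portfolios is the cell-overlap percentage
(whole-portfolio: |A∩B|/|A|, symmetrised by the minimum of the two
directions; per-class mode restricts to stated land-cover classes under
each portfolio's own scenario map and averages over classes, reporting
both directions).

## Land-cover futures

Scenarios form the 2 × 2 × 3 factorial of vegetation-dynamics regime
(moderate / severe climate change), urban policy (regulated /
unregulated) and development rate (×1 / ×4 / ×8 on the urban
probabilities only), simulated for 60 years of synchronous annual raster
updates: urban expansion into built-adjacent (Moore) cells, urban patch
seeding away from built land (unregulated only), formation succession or
regression, and fire (severe regime, per-cell ignition without spread,
reset to herbaceous). Built-up land is absorbing; agricultural classes
urbanise but never undergo vegetation transitions; protected cells are
exempt from urbanisation. A rate-multiplied probability above 1 is a
configuration error, never clamped.

Vegetation transitions are, by default, *patch-boundary conditioned*: a
formation transition applies only to cells with a Moore neighbour already
in the target formation, so succession and die-back advance as coherent
fronts (~1 cell per decade at the default rates) instead of scattering
independently. Unconditioned (plain Bernoulli) transitions remain
available and are the semantics of the one-step binomial checks.

Default annual rates were chosen against three observables: the baseline
(×1) scenario reproduces modest decadal urban growth (~10% built-area
growth over 60 years) while ×8 roughly triples built cover; the moderate
regime gains woody cover while the severe regime loses it; and the
vegetation-map divergence between the two regimes after 60 years
(~60% per-class overlap) matches the divergence reported between
moderate and severe climate-change simulations of comparable
Mediterranean systems.

## What the synthetic generator emulates — and what it does not

The generators reproduce the statistical structure the analysis assumes,
not any real geography:

* a 13-class categorical raster (64 × 64 cells of 1 km by default,
  4,096 km²) dominated by agriculture and built-up land (~57%), with the
  five successional Mediterranean formations a scarce ~30%; clumping by
  rank-thresholding a Gaussian-smoothed noise field, with the class
  quantile-band order randomised per seed so built-up land can adjoin
  any class;
* species ranges constant over atlas-style blocks (8 km default),
  right-skewed in size (widespread-dominated with a rare tail, as in
  regional breeding-bird atlases) and guaranteed, via a documented
  retry rule (sub-seed `seed + 10007·attempt`, ≤ 10 retries), to
  exercise every branch of the target rule the landscape's formation
  area makes reachable;
* associations in contiguous successional-rank guilds (1–3 strong plus
  0–2 moderate formations, breadth growing with range size), strong and
  moderate pooled and restricted to natural classes;
* clumped protected areas (15% default) biased toward formations, as
  statutory reserves are.

Not emulated: real vector geography, stream/cliff buffering, atlas
density classes, road networks or zoning attractors, dispersal, fire
spread, or land-price variation (cost is area). Passing tests therefore
demonstrate the pipeline's internal correctness and the qualitative
behaviour of the method on landscapes with this structure — not
quantitative predictions for any real region.

A replicated end-to-end experiment (20 master seeds at the default desk
scale) compares the three strategies. In these conditions the directional
advantage of scenario-informed portfolios over the current-distributions
portfolio is *not* consistently reproduced: a falsification control with
identity scenarios shows the aggregation and budget accounting to be
exactly fair, and scenario information is demonstrably valuable
(portfolios re-ranked by a single scenario's frequencies outperform the
current portfolio in changed scenarios, and CV aggregates hold 25–30%
less future-urbanised area), but the budget — fixed by definition at the
natural area of the present-day >0.9-frequency core — is systematically
smaller than the scenario-essential PU sets, and capped targets make
range-restricted species automatically covered by the incumbent
footprint. At this problem size those two forces dominate: in the
20-replicate experiment the current portfolio matches or exceeds the
all-scenarios portfolio in most replicates — the reverse of the
full-scale ordering — and the corresponding acceptance test is left
failing rather than weakened, since it documents a real scale limitation
of the desk-sized study conditions.

## Numerical choices and degenerate inputs

* Exact class proportions by largest-remainder apportionment of cell
  counts; realized mixes deviate only by integer rounding.
* Population SD (n divisor) throughout (CV ranking, performance
  summaries); CV of a never-selected PU is undefined and the PU is
  excluded from ranking.
* Coverage and calibration comparisons use a 1e-9 absolute tolerance on
  areas; threshold comparisons (0.9 frequency, 50% lock shares) are
  strict inequalities.
* Annealer ties: first-seen best kept; brute force prefers smaller then
  lexicographically smallest selections.
* Zero-habitat species get zero targets and drop out of the objective;
  problems with no available PUs return the locked-in-only solution.
* MARXAN-dialect files store floats with `repr` precision and are parsed
  with round-trip float conversion, so write/read reproduces a problem
  bit-exactly.

## Problem sizes

Defaults are desk-scale: 64 × 64 cells, 24 species, 100 restarts ×
20,000 iterations with SPF calibration at 10 restarts × 5,000 iterations,
chosen so a full replicate (13 selection problems) completes in tens of
seconds and the 20-replicate experiment in minutes. The full-scale
settings of the original study design (1,000 restarts × 1,000,000
iterations, thousands of PUs) are configuration presets, not defaults.
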