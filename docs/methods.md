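# Methods

`islereserve` evaluates how well an island's protected-area (PA) network
serves its endemic species under climate change, and how well it *could*
serve them. The pipeline has five stages: simulate a study system, project
species distributions for a baseline and a future period, measure what the
current reserves cover, optimize alternative reserve networks, and score
the current reserves against those optima and against chance.

## Species distribution modelling

Species enter as presence records on the island raster (500 m nominal cell
size). Presence-only records are complemented with pseudo-absences drawn
uniformly from island cells without presences, one per presence, so
prevalence in the evaluation sample is 0.5. Species with fewer than 15
presences are excluded (five points per climatic covariate; the floor is
configurable).

Each candidate suitability model is scored over **ten random 80/20
calibration/validation splits** (presences and pseudo-absences split at the
same fraction so both classes appear in every validation set) with the True
Skill Statistic,

```
TSS = sensitivity + specificity − 1 ∈ [−1, 1],
```

where 1 is perfect agreement and ≤ 0 is no better than random. A member's
score is its mean TSS across the ten splits; members with mean TSS < 0 are
discarded, survivors are refit on the full record set, and a cell is
present in the **consensus** map iff at least half of the retained members
predict presence there (with two members this is a union; the comparison is
`count ≥ n/2` with real division, the literal reading of "at least half").
The discard decision is taken per averaged member, not per split — the
alternative is a flagged sensitivity choice. Projection to the future
period reuses the fitted parameters unchanged.

Two reference model families stand behind the pluggable interface:

* **rectilinear envelope** — presence iff every covariate lies inside the
  [min, max] box of the calibration presences. Zero omission on training
  data by construction; sensitive to outlying presences (a reason the
  generator treats false presences as negligible, see below).
* **standardized-distance centroid** — Euclidean distance to the presence
  centroid after per-covariate standardization, thresholded at the largest
  calibration-presence distance (zero-omission threshold).

The three covariates — maximum annual temperature `tmax` (°C), minimum
annual precipitation `ppmin` (mm), annual precipitation range `prange`
(mm) — are taken as given; no variable selection is performed. Finer
climate rasters are brought onto the species grid by block mean
(continuous) or block majority (binary; ties resolve to presence because a
false absence is the costlier error downstream; partial trailing blocks are
padded with nodata).

## Gap analysis

For each species and period, the **protected proportion** is
|range ∩ PA| / |range|. The **in-reserve loss** between periods is
(|t₁ ∩ PA| − |t₂ ∩ PA|) / |PA|, oriented so contraction is positive; gains
are reported as negative losses, not clipped. Group summaries report
arithmetic mean ± sample standard deviation (n − 1), in percent; a
singleton group gets sd = 0 with a warning. Species whose projected future
range is empty are excluded from future-period analyses only, each
exclusion logged. Richness maps are per-cell layer counts.

## Reserve optimization

A binary protection raster is optimized directly with a genetic algorithm;
all operators act on the raster.

* **Fitness.** Minimum set: infeasible (null sentinel, −∞) unless every
  species reaches its target; otherwise −w_cost·(cost/area) +
  w_conn·connectivity. Maximum coverage: infeasible over budget; otherwise
  w_repr·(weighted mean of min(rep_s/target_s, 1)) + w_conn·connectivity.
  Connectivity is rook-adjacent protected pairs / 2k for k protected cells,
  a [0, 1] compactness score. Defaults w_repr = w_cost = 1, w_conn = 0.05:
  on desk-scale instances a one-cell cost difference dominates any
  connectivity difference, so cost remains the primary criterion.
* **Targets.** The scalar target is the proportion of each species' range
  to protect; per-species targets may be supplied instead (a zero target
  leaves a species unconstrained). Species weights w_s (e.g. for
  single-island endemics, SIE) scale targets as
  `target_s = min(1, base_s · w_s / mean(w))` and also weight the
  maximum-coverage attainment term.
* **Operators.** Tournament selection (size 2) with elitism 1; crossover
  (rate 90/100 per pair) swaps a random rectangular window between
  parents; mutation (rate 50/100 per offspring) reassigns one random
  island cell, adopting the majority class of its rook neighbours with
  bias 0.8 (ties flip) so patch edges grow or contract preferentially;
  two random immigrants per generation maintain diversity.
* **Memetic local search.** Each new minimum-set incumbent is pruned
  (redundant cells removed while fitness improves) and, on instances of
  ≤ 100 cells, refined by a one-for-one swap neighbourhood with a bounded
  plateau walk — the remove-two-add-one moves single-cell mutation cannot
  compose. The initial population contains the greedy solution and the
  trivial feasible point; callers may inject known candidates (the
  pipeline injects the current PA network).
* **Scale.** Full-scale defaults are population 1000 for 100 000
  generations; all tests and the shipped analyses run the reduced
  configuration (population 40, 2000 generations, or fewer where stated),
  which suffices for the problem sizes used here (≤ 1600-cell islands,
  ≤ 24 species) — chosen as the package's desk-scale working point.
* **Oracles.** `exhaustive_minimum_set` / `exhaustive_maximum_coverage`
  enumerate subsets (guard: ≤ 25 cells; minimum set restricts enumeration
  to cells inside some range, exact because a minimum-cardinality set
  contains no useless cell; ties break by connectivity then lexicographic
  order). `greedy_baseline` adds the cell with the largest marginal
  weighted-target gain. Both are yardsticks, never the implementation.

A single seeded generator drives each run; the same seed and configuration
reproduce the returned raster bit for bit, and elitism makes the best
fitness non-decreasing over generations.

## Efficiency and null models

Two ratios compare the current PAs with the quasi-optimal solutions, both
in [0, 1] with 1 meaning the current reserves are as good as the best
solution found:

* **Minimum set**: optimal cost / current cost. The pipeline sets each
  species' target to the proportion of its range the current reserves
  already protect (SIE weights scale these targets), so the current
  network is feasible by construction and the ratio cannot exceed 1. The
  reported quasi-optimal cost is the best among the candidates examined
  (GA incumbent and the PA itself — the GA's fitness may trade a few
  cells for compactness on large islands).
* **Maximum coverage**: current % of targets reached / quasi-optimal % of
  targets reached, under a budget equal to the current PA size and a
  scalar target equal to the (weighted) mean current protected
  proportion. A target counts as reached only when representation meets
  it — no partial credit. The current network is itself a feasible
  candidate, so the quasi-optimal percentage is at least the current one.

For the SIE-weighted pass the weights enter the mean that defines the
scalar target (coastal, poorly covered SIEs pull it down) and the
maximum-coverage objective; per-species target inflation is deliberately
not used there because it can demand more than any network of the PA's
size delivers, which would push the ratio above 1. The weight's default is
5; the appropriate value is a judgement call and is exposed in the config.

The **null model** is simple random resampling: each replicate protects
the same number of cells drawn uniformly without replacement from the
island (per-species protected counts are then hypergeometric, mean
n_protected/n_island). Defaults: 999 replicates, two-sided α = 0.05.
A species is "higher" than null if its observed proportion exceeds the
(1 − α) null quantile, "less" below the α quantile, "equal" otherwise —
the non-rejection region, since exact ties have probability ≈ 0.

## Synthetic study generator

No real species or climate rasters ship with the package, so a generator
produces study bundles with known truth:

* **Island**: smoothed random radial coastline (low-order harmonics) with
  elevation rising from 0 at the coast to ~1000 m inland; 40×40 cells by
  default (~740 island cells at nominal 500 m).
* **Climate**: elevation-driven surfaces — tmax cools at −0.0065 °C/m from
  22 °C at sea level; ppmin and prange rise with elevation. The future
  period adds a warming delta (+2.5 °C default) and scales ppmin by a
  drying factor (0.85); prange carries over. Future ranges therefore
  contract and shift upslope mechanistically, through fixed niches — not
  by deleting cells.
* **Species**: 24 by default (4 bryophytes, 8 vascular plants,
  12 arthropods), each a climate-envelope niche anchored at a random
  island cell. The tmax width is 0.35–0.8 of the island-wide spread —
  ranges are climatic bands, not the whole island — while the
  precipitation widths are broader (1–2×): distributions are primarily
  thermally limited. Three SIEs get narrow (×0.35), coastal-anchored
  niches (restricted, warm-edge ranges). Omission noise 2%; commission
  noise 0 — curated endemic atlas records carry negligible false
  presences, and scattered false presences would inflate envelope models
  to island-wide boxes, which real consensus maps do not show. Candidates
  below the 15-cell floor are redrawn (≤ 50 tries, then flagged).
* **Protected areas**: 15% of the island in 3 rook-connected patches grown
  from seeds biased to high interior ground (reserves on mountain forest),
  which is what makes protected proportions *rise* between periods as
  ranges contract toward the interior while in-reserve loss stays
  positive.
* **Calibration mode** (`pa_contraction = f`): baseline ranges are forced
  to cover the reserves and future layers equal the baseline thinned
  inside the reserves with probability f. Because the loss statistic
  divides by |PA|, this is the configuration in which its mean across
  species equals f exactly in expectation — used to validate the
  statistic's recovery of a known parameter.
* **Occurrence sampling**: detection probability 0.8 per occupied cell,
  topped up to the 15-record floor when the range allows.

Everything derives from one seed via independent spawned streams; a bundle
regenerates bit-identically from its config and seed.

### What the generator does and does not emulate

It reproduces the *structure* the analysis assumes — aligned rasters, two
periods, elevation-correlated climate, range contraction, patchy interior
reserves, range-restricted coastal endemics — with fully known truth. It
does not emulate real topography or climatology, dispersal limitation,
biotic interactions, spatially autocorrelated sampling effort, or
registration error between layers. Passing tests therefore demonstrate
that the statistics and optimizers do what they claim on data with the
assumed structure, not that the ecological conclusions transfer to any
particular real island. Under the default warming, roughly a quarter to a
third of synthetic species (including the coastal SIEs) lose all suitable
climate space and are excluded from future-period analyses by the same
rule the pipeline applies to real data.

## Numerical choices and degenerate inputs

Feasibility comparisons use an absolute tolerance of 1e-9 on proportions.
Majority ties (resampling, consensus "at least half", mutation
neighbourhoods) each have a single documented rule (presence / presence /
flip). Empty protection has connectivity 0. Proportions are undefined (an
error) for species with empty ranges; callers filter first. All-nodata
resample blocks stay nodata. The ESRI ASCII reader names the offending
line on malformed input; round-trips are exact at the printed precision.

## Known limitations

* The two reference suitability models are deliberately simple; TSS values
  on synthetic bands are optimistic compared with noisy real data.
* The GA's oracle-verified regime is small instances; at hundreds of cells
  its solutions are quasi-optimal only, which is why the efficiency
  reports take the best examined candidate rather than trusting a single
  run.
* With per-species targets equal to current proportions, the current PA
  lies exactly on the feasibility boundary, so baseline minimum-set
  efficiency is frequently 1.0 on desk-scale bundles (every PA cell
  touching a range is non-redundant at those targets).
* Null-model "equal" verdicts depend on α and the replicate count; with
  999 replicates the quantiles are stable to ~1/999.
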