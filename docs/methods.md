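# Methods

This note documents the models, estimators and numerical choices behind
`nichepart`, and what the synthetic-data generator does and does not
emulate.

## The analysis model

The package treats a breeding-season tracking study of two sympatric
central-place foragers as four parallel composition analyses plus a
space-use analysis:

1. **Geographic foraging area.** Fixes with tag-reported ground speed
   strictly below 4 m/s are *standing points* (foraging/perching proxy).
   Standing points within a species-specific nest radius (defaults
   0.15 km for the near-nest species, 1.5 km for the commuter) are
   attributed to social/nest activity and removed; a grid point-density
   filter then removes *flight corridors* (cells whose standing-point
   count falls below the q-th quantile of nonzero cell counts; defaults
   cell = 500 m, q = 0.5 — the corridor-exclusion method is standard but
   no published threshold exists, so both are exposed in `QCPolicy`).
   Per-individual quality control drops sets with fewer than 51 points
   and individuals whose nest failed before chick-rearing; individuals
   tracked over two consecutive similar seasons (seasonal UDOI > 0) are
   summarized by the two-season mean.
2. **Foraging-habitat type.** Land-cover class is sampled under each
   standing point (point-in-cell lookup; no polygon-area weighting, which
   is more robust than overlaying the whole home-range polygon); per
   individual this yields class-use proportions compared against
   study-area availability with one-sample t tests.
3. **Diel timing.** For high-frequency (5-min) individuals only, the
   proportion of in-foraging-area fixes per hour bin [h, h+1),
   h = 7…18. The duty cycle (06:55–19:05) only partially covers the
   hours before 07:00 and after 19:00, so those fixes are excluded.
4. **Diet.** Per-nest prey-taxon counts; nest-years with fewer than 8
   items are dropped, and multi-year nests are averaged per taxon to
   avoid pseudo-replication of territories.

Season windows: analyses run on each species' *whole* season and on the
*shared* window (default Mar 25 – Jul 15, boundary days inclusive; dates
are configuration because breeding phenology varies).

All boundary conventions are strict (`<` 4 m/s, `<` nest radius, `<` 8
items, `<` 51 points), matching the way such thresholds are stated in
field protocols.

## Space use

The utilization distribution is a fixed-bandwidth isotropic bivariate
Gaussian KDE with the smoothing factor h interpreted as the kernel σ (the
`adehabitat` convention), evaluated at cell centers of a square grid and
stored as cell masses (density × cell area, renormalized). Numerical
choices: cell ≤ h/5; per-point kernels truncated at 6h (neglected mass
< 1e-8); grid padded 5h beyond the point bounding box so edge truncation
is negligible (< 2e-6 of mass). Midpoint evaluation of Gaussians is
essentially exact at these resolutions (Poisson-summation error
≪ 1e-12), which the single-point analytic test exploits.

The p-isopleth ranks cells by density and takes the smallest set whose
cumulative mass reaches p, *including ties with the threshold cell* — so
a uniform UD's isopleth is its entire support and the
identical-uniform-UD overlap identity (UDOI = 1) holds exactly. Area is
cell count × cell area; contour polygonization (for GeoJSON export) is
cosmetic and never used for area.

UDOI(1,2) = A₁,₂ · Σ(m₁·m₂)/cellArea with A₁,₂ the intersection area of
the two 95 % isopleths; both UDs must share a grid (the pipeline
evaluates every individual on one common grid). Values can exceed 1 for
concentrated joint use; for the arcsin-√ ANOVA across pair groups they
are clipped to [0, 1] and exceedances counted.

## Dyadic attraction–repulsion

The index compares the observed number of space–time meetings (fix pairs
within 500 m and 150 s; both configurable) against a null of circular
time-shifts of one track, which preserves each track's autocorrelation
and spatial footprint. Two refinements proved necessary and are part of
the contract:

* shifts are quantized to whole days whenever the common observation
  span allows (≥ 3 days): a continuous shift moves duty-cycled (daytime
  only) fixes into night slots where the partner has no fixes, which
  biases every diurnal pair toward apparent attraction;
* shifts are additionally quantized to the shifted track's median fix
  interval: regular tag schedules mean a phase-breaking shift admits no
  temporal match at all within the tolerance, biasing the null low.
  With both refinements, 300 independent random-walk pairs score a mean
  index of 0.51.

The index is the (tie-adjusted, add-one) rank of the observed count in
the null: 0.5 neutral, ≤ 0.25 reported as repulsion, ≥ 0.75 as
attraction. Pairs with no common observation period are reported blank.
Note that genuinely co-occurring tracks — e.g. two random walks started
at the same point — *are* attracted under this definition; neutrality
calibration requires independent starting positions.

## Community and niche statistics

* **Bray–Curtis** via `scipy.spatial.distance`; no pre-transformation by
  default (a `transform` hook exists because comparable software often
  √-transforms abundances, which changes every similarity downstream).
* **nMDS**: non-metric SMACOF (scikit-learn) over seeded random starts,
  reporting Kruskal stress-1 recomputed by isotonic regression of
  configuration distances on dissimilarity ranks. The SMACOF stopping
  tolerance defaults to 1e-9: looser tolerances stall visibly above the
  true minimum on near-perfectly-embeddable configurations. Because the
  monotone fit is weak (ties allowed), zero stress does not force a
  strictly rank-perfect configuration.
* **ANOSIM**: R = (r̄_between − r̄_within)/(M/2) on midranked
  dissimilarities, M = n(n−1)/2; p by label permutation with the add-one
  convention. An exact-enumeration variant over distinct label
  assignments backs the tests; note the smallest attainable p is
  2/C(n, n_a), e.g. 0.1 for a 3+3 design.
* **SIMPER**: per-category between-group contribution is the cross-pair
  mean of |xⱼ−yⱼ|/Σₖ(xₖ+yₖ) expressed as % of the overall mean
  dissimilarity (sums to 100); within-group typicality decomposes
  similarity as Σ 2·min(xⱼ,yⱼ)/Σ(xₖ+yₖ). Identical groups return an
  explicit empty result.
* **Pianka** O_jk is the cosine similarity of proportion rows (computed
  that way for speed); the between-species value is reported both as the
  mean over cross pairs and on pooled group profiles (the pooled value
  is the headline, since a single published overlap per comparison does
  not disambiguate the two).
* **RA3 null**: each iteration independently permutes every row's values
  across all resource categories — niche breadth (Σp²) is exactly
  preserved, which category is used is randomized. Both tails are
  reported with the add-one convention (the published use of such nulls
  does not state its tail convention).
* **Levins' B** is unstandardized 1/Σp² (published breadth values > 1
  rule out the standardized form).
* **Chao1 / rarefaction**: S_obs + F₁²/(2F₂), bias-corrected
  S_obs + F₁(F₁−1)/2 when F₂ = 0. The sample-based curve bootstraps
  m-nest subsets without replacement (default 1000 resamples in the
  library, 500 in the pipeline). Pooled counts are rounded to integers
  before the singleton/doubleton tally because per-nest values may be
  multi-year means; any taxon with positive pooled mass counts at least
  1 so rounding never deletes an observed taxon.
* **Combined score**: product of per-axis (1 − mean between-species
  Bray–Curtis dissimilarity), reported raw and at 2 decimals.

## The synthetic generator

The generator is phenomenological: each fix gets a behavioural state
(forage / transit / nest), then a position and a tag-style ground speed
consistent with that state. It is *not* a mechanistic movement model —
no aerodynamics, no continuous paths between consecutive fixes — because
the analysis consumes only positions, speeds and times.

Default conditions (two species, one season, planar meters):

* 9 near-nest ("LLB") and 8 commuting ("STE") individuals on a 40 km
  landscape with four habitat classes at availability 0.30/0.12/0.37/0.21;
  6 + 2 of them carry 5-min solar tags, the rest 90-min regular tags;
  duty cycle 06:55–19:05 (147 fixes/day at 5 min).
* Near-nest species: 3 individual patches at N(2.35, 0.62) km from the
  nest, uniform diel activity, season Mar 25 – Jul 15 (nested in the
  shared window, so whole ≡ shared for this species). Commuting species:
  a species-level pool of 6 shared foraging grounds (radius 1.5 km) at
  N(13.03, 2.20) km from the colony centroid, 4 grounds per individual,
  one ground used only after the shared window (so whole-season areas
  exceed shared-window areas); midday-peaked activity (truncated
  Gaussian over hours, peak 13:00, σ 2 h, baseline floor 0.3 — the
  floor keeps both species active all day, as diurnal raptors are; the
  Gaussian shape itself is a stand-in, since no distributional form for
  within-day activity is published).
* Transit fixes lie along the nest–ground segment with 200 m lateral
  jitter and truncated-normal speeds ≥ 4 m/s; 2 % of them are slow
  corridor rests, which is what the density filter must remove. Forage
  positions sample a habitat class from the species use vector
  (0.41 low-natural-vegetation / 0.12 cultivated for the resident;
  0.07 / 0.59 for the commuter) and then a cell of that class within the
  patch.
* Diets: 53 taxa (20 common + a rare tail), generalist pool of 48 vs
  specialist pool of 34 with 29 shared; per-nest taxon probabilities are
  Dirichlet(15 × species vector) — the concentration reproduces
  field-scale between-species Bray–Curtis dissimilarity (~70 %) — and
  nest-year counts are multinomial with ~39 / ~24 items per nest-year;
  12 % of nest-years are deliberately under-sampled (< 8 items) to
  exercise the diet filter; 10 % of nests fail before chick-rearing.

Everything above is configuration (`SimConfig` / `SpeciesParams`), and
runs are byte-identical given the seed (all streams derive from it).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: GPS positional error and fix loss, behaviour
misclassification at the 4 m/s threshold (simulated speeds are drawn
from the state, so the threshold is almost noiseless), within-season
phenology of movement, spatial autocorrelation of land cover (cells are
iid), prey-availability gradients across territories, and inter-annual
site fidelity (a single tracked season is generated).

## Problem sizes and determinism

The default pipeline run processes ~157k fixes over 17 individuals,
100 nests and ~2.7k diet records; the full test suite runs in about two
minutes and the acceptance script in under a minute. Pipeline-level
Monte-Carlo sizes (999 ANOSIM permutations, 1000 RA3 iterations, 500
rarefaction bootstraps, 199 attraction permutations per pair, 10 nMDS
starts) are the package's chosen defaults for a single-CPU run and are
all exposed in `PipelineOptions`. Every stochastic component takes an
explicit seed; the pipeline derives stage seeds from the run seed, and
identical configurations produce byte-identical outputs.

## Known limitations

* The local equirectangular projection used for lon/lat input is
  accurate to ≪ grid resolution at study scales (≤ ~200 km) but is not a
  conformal national grid; supply projected coordinates for larger
  extents.
* Isopleth areas are cell-count areas, not polygonized-contour areas;
  the two differ by less than the grid resolution on smooth UDs
  (the grid-refinement test bounds this at < 2 %).
* The attraction index's day-quantized null needs ≥ 3 common tracking
  days; shorter overlaps fall back to interval-quantized continuous
  shifts.
* UDOI between species is near zero in the default synthetic scenario
  (the commuter's grounds lie far outside the resident's ranges), so the
  between-group ANOVA contrast is driven by the within-group difference.
* Exact replication of published inferential statistics that depend on
  the original field data (Mann–Whitney Z, repeated-measures F values,
  specific ANOSIM R values) is out of scope; the pipeline reproduces the
  *structure* (directions, orderings, ratios) of those results on
  synthetic data.
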