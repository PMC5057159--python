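# nichepart

Multi-axis niche-differentiation analysis for GPS-tracked central-place
foragers.

`nichepart` quantifies how two sympatric predators partition their
ecological niche along four axes — **geographic foraging area**,
**foraging-habitat type**, **diel foraging timing**, and **diet** — from
the data a breeding-season field study typically produces: Movebank-style
GPS fix tables, nest locations, a categorical land-cover raster, and
per-nest prey tables. The motivating system is a pair of raptors (a
buzzard-like resident that forages ~2.4 km from its nest and a
snake-eagle-like commuter that travels ~13 km along flight corridors to
shared foraging grounds), but every threshold and parameter is
configuration, not code.

A first-class synthetic-data generator reproduces the statistical
structure the analysis assumes — two-state central-place movement with
tag-reported ground speeds bimodal around 4 m/s, a 12 h duty cycle
(06:55–19:05) at 5-min or 90-min fix schedules, uniform vs midday-peaked
diel activity, habitat preference/avoidance against availability, and
Dirichlet-multinomial diets with configurable inter-species overlap — so
the full pipeline is testable end-to-end with no data download.

## Methods at a glance

* **Standing points**: a fix is a foraging/perching proxy when its
  tag-reported ground speed is < 4 m/s; points within the
  species-specific nest radius (0.15 / 1.5 km) are social, not foraging,
  and a point-density filter removes sparse *flight-corridor* cells.
* **Foraging area**: fixed-bandwidth Gaussian kernel utilization
  distribution (smoothing factor h ∈ {250, 500, 1000} m = kernel σ);
  the foraging area is the 95 % isopleth (smallest cell set holding 95 %
  of the UD mass). Pairwise overlap uses the Utilization Distribution
  Overlap Index, UDOI = A₁,₂ · ∫∫ UD₁·UD₂ dx dy, compared across
  within/between-species pair groups by one-way ANOVA on
  arcsin-√-transformed values.
* **Composition statistics** (applied identically to habitat, hourly
  activity 07:00–19:00, and diet matrices): Bray–Curtis dissimilarity
  d(x,y) = Σ|xᵢ−yᵢ|/Σ(xᵢ+yᵢ), non-metric MDS with Kruskal stress-1,
  ANOSIM Global R with permutation p, SIMPER contribution decomposition,
  UPGMA similarity grouping.
* **Niche metrics**: Pianka overlap O_jk = Σpᵢqᵢ/√(Σpᵢ²Σqᵢ²) with an RA3
  randomization null (within-row permutation over resource categories,
  retaining niche breadth); Levins breadth B = 1/Σpᵢ²; Chao1 richness
  S_obs + F₁²/(2F₂) with sample-based bootstrap rarefaction.
* **Dyadic interaction**: k-means clustering of foraging locations with
  per-cluster species composition; an attraction–repulsion index per
  track pair (observed space–time meeting count ranked within a circular
  time-shift null; 0.5 neutral, → 1 attraction, → 0 avoidance); nest
  nearest-neighbour distances.
* **Combined segregation score**: the product of per-axis between-species
  Bray–Curtis similarities — small products mean strong multi-axis
  segregation even when single-axis overlap is high (niche
  complementarity).

## Worked example

Run the full pipeline on the default synthetic two-species study:

```python
from nichepart.config import SimConfig
from nichepart.pipeline import run_all, PipelineOptions, table1_ratios

results = run_all(config=SimConfig(seed=1), out_dir="outputs",
                  options=PipelineOptions())
print(table1_ratios(results["table1"]))
print(results["combined"])
```

prints

```
{'distance_ratio': 5.1, 'area_ratio_whole_h250': 4.0,
 'area_ratio_whole_h500': 2.9, 'area_ratio_whole_h1000': 2.5,
 'area_ratio_shared_h250': 3.6, 'area_ratio_shared_h500': 2.6,
 'area_ratio_shared_h1000': 2.2}
{'axes': {'diet': 0.3027, 'habitat': 0.5090, 'timing': 0.8452},
 'product': 0.1302, 'product_rounded': 0.13}
```

The commuting species forages 5.1× farther from its nest than the
resident and uses a 2.2–4.0× larger 95 % foraging area (depending on the
smoothing factor and season window). The three remaining axes overlap
0.51 (habitat), 0.85 (timing) and 0.30 (diet); their product, 0.13, is
the combined similarity — strong overall segregation despite the large
overlap in foraging hours. `outputs/` then contains `table1.csv`
(per-species distance and area summaries), `table2.csv` (qualitative
four-axis summary), `overlap_report.csv` (pairwise UDOI),
`nullmodel_report.csv` (Pianka + RA3 tails), `diet_report.csv` (richness
and breadth), `interaction_matrix.csv`, an exclusion log and a run
manifest.

The same run from a shell:

```sh
nichepart run-all --seed 1 --out outputs
nichepart synthesize --seed 1 --out synthetic_data
nichepart tracks --fixes synthetic_data/fixes.csv \
    --nests synthetic_data/nests.geojson --window shared \
    --out standing_points.csv
```

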