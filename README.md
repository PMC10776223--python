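# raptorhotspots

Movement-based bioindication for farmland landscapes: designate *activity
hotspots* of GPS-tracked birds of prey on a 50 m grid, pair each with a
matched *control site* 500 m away, and test whether biodiversity survey
metrics (bird, small-mammal and amphibian abundance and richness, plant
richness and within-plot similarity) discriminate the two site classes.

The idea: avian predators integrate information about prey abundance and
diversity over whole landscapes. Where several individuals of several raptor
species concentrate their foraging, the ground below should hold more small
prey and more diverse vegetation. Multi-individual, multi-species GPS
telemetry therefore acts as a spatially precise biodiversity indicator —
if the designation procedure and statistics bear that out. This package
implements that analysis pipeline end to end, plus a synthetic-data
generator with planted ground truth so every stage can be validated without
field data.

## The method

**Designation.** Tracks are thinned to 15-minute intervals (a fix is kept
when it is at least `interval − tolerance` after the previous kept fix) so
well-charging loggers do not dominate. The study area is divided into
50 m × 50 m cells; forest, water and peatland cells are subtracted. Per cell
and season the pipeline tallies n<sub>obs</sub>, n<sub>individuals</sub>,
n<sub>species</sub> and n<sub>days</sub> (revisits). A cell is a hotspot
candidate when **n<sub>individuals</sub> ≥ 3 and n<sub>species</sub> ≥ 2**;
adjacent candidates collapse to the cell with the most species (ties: more
individuals, then more observations); cells with isolated perch structures
are discarded; accepted hotspots keep ≥ 450 m spacing. Each hotspot's
control is found by scanning the cells intersected by the 500 m circle
around its centroid clockwise from north, taking the first farmland cell
with ≤ 1 raptor observation that lies ≥ 500 m from every other designated
site. Every tie-break is deterministic, so designation is exactly
reproducible.

**Statistics.** Each survey metric *x* enters a single-predictor binomial
GLM, logit P(hotspot) = β₀ + β·x (predictors z-scored by default), reported
with Wald 95% CI and p, AIC, McFadden's R² = 1 − lnL/lnL₀ and Nagelkerke's
pseudo-R². Hotspot persistence in later years is tested per usage metric
with a two-sided Wilcoxon rank-sum test (exact null distribution for small
tie-free groups, otherwise a tie- and continuity-corrected normal
approximation).

**Simulation.** Synthetic worlds have a clustered landcover mosaic
(farmland ≈ 46%, forest ≈ 45%), circular prey-rich patches, and
central-place foragers whose trip destinations are drawn with probability ∝
(patch quality)^α. Survey counts are negative binomial with means multiplied
by δ inside patches. α = 0 and δ = 1 are exact nulls; large α and δ > 1
plant a recoverable signal.

## Worked example

```python
import numpy as np, raptorhotspots as rh
from datetime import date
from raptorhotspots.surveys import table1_frame

rng = np.random.default_rng(3)
landscape = rh.generate_landscape(seed=rng)                       # 5 km x 5 km, 12 prey patches
tracks = rh.generate_tracks(landscape,
                            rh.MovementConfig(attraction_exponent=4.0), seed=rng)
thinned = rh.resample_tracks(tracks)                              # 15-min thinning
window = rh.SeasonWindow("spring2020", date(2020, 4, 1), date(2020, 4, 30))
grid = rh.build_grid(landscape.bbox, 50.0)
usage = rh.tally_usage(thinned, grid, window)
result = rh.designate_sites(usage, landscape.mask_for(grid))
print(len(tracks), len(result.pairs))                             # 9162 fixes, 12 pairs

sites = [s for p in result.pairs for s in (p.hotspot, p.control)]
plots = rh.generate_surveys(landscape, sites,
                            rh.SurveyEffectConfig(effect_multiplier=2.0), seed=rng)
frame = table1_frame(rh.run_table1(rh.aggregate_surveys(plots)))
print(frame[["predictor", "beta", "ci_low", "ci_high", "p", "n"]].round(3))
```

prints

```
          predictor   beta  ci_low  ci_high     p  n
     bird_abundance  2.450   0.691    4.209 0.006 24
      bird_richness  2.666   0.661    4.671 0.009 24
   mammal_abundance  1.754   0.347    3.162 0.015 24
    mammal_richness  0.877  -0.144    1.899 0.092 24
amphibian_abundance  1.185   0.075    2.294 0.036 24
 amphibian_richness  0.890  -0.118    1.898 0.084 24
   plant_similarity -2.427  -4.241   -0.612 0.009 24
     plant_richness  0.768  -0.231    1.767 0.132 24
```

With a doubled survey mean inside patches (δ = 2) all fauna slopes are
positive and the plant-similarity slope is negative: plots that raptor
movement flags as hotspots carry more animals, more species, and more
heterogeneous vegetation. The slopes are per standard deviation of the
predictor; n counts the surveyed plots (12 hotspot + 12 control).

The same pipeline runs from the shell on files
(`raptorhotspots simulate | designate | stats | persistence | run-all`);
field data enter as a GPS fix CSV (canonical or Movebank columns), landcover
GeoJSON with a `class` attribute, and per-taxon survey CSVs whose schemas
are documented in `raptorhotspots.pipeline.SURVEY_SCHEMAS`.

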