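# Methods

This note records the models, conventions and design choices behind the
package, including the points where the underlying study design left room
for interpretation.

## Coordinate and grid conventions

All internal coordinates are projected metres. Geographic input
(Movebank-style longitude/latitude) is projected on read with a local
equirectangular approximation centred on the data's mean position
(x = R·cos φ₀·Δλ, y = R·Δφ). At landscape extents of tens of kilometres the
distortion is far below the 50 m cell size, which is the resolution
everything downstream operates at.

Cells are (row, col), 0-based, origin at the lower-left of the bounding box;
cell (r, c) covers the half-open square [x₀+c·s, x₀+(c+1)·s) ×
[y₀+r·s, y₀+(r+1)·s). A point exactly on a shared edge belongs to the
higher-index cell. The grid is aligned to the study-area bounding box, not
to any national grid. Timestamps are stored in UTC; calendar dates (season
membership, revisit counting) are extracted in a configurable timezone,
default UTC.

## Track thinning

The 15-minute resampling is greedy: the first fix of an individual is kept,
and thereafter a fix is kept iff it arrives at least `interval − tolerance`
after the previous kept fix (defaults 15 and 2 min). This is the standard
track-regularization used in movement ecology toolkits; it is idempotent and
avoids the adjacent-bin artifacts of keep-first-fix-per-bin schemes. The
tolerance absorbs logger jitter; both values are configurable. No
fix-quality (HDOP) or speed filtering is applied, and no nest-vicinity
exclusion — the designation criteria themselves (several individuals of
several species in one 50 m cell) make single-nest artifacts unlikely.

## Landcover masking

A cell's class is the landcover class with the largest area overlap. The
cell is eligible when that class is open land (farmland or other open); any
tie for the largest class — including a cell covered by no polygon — makes
the cell ineligible, a deliberately conservative reading of "subtracting"
the closed-landcover layers. `farmland` is a stricter flag (largest class is
farmland exactly); controls require it, hotspot qualification only requires
eligibility. Perch structures (isolated trees, pylons) are an input point
layer; a flagged cell can never be a hotspot or control. Detecting perches
automatically is out of scope — in the field protocol they were identified
by inspection.

## Designation

Qualification is read as n_individuals ≥ 3 AND n_species ≥ 2 — the weakest
condition consistent with "at least three different individuals of two
different species"; both thresholds are configurable. Adjacent qualifying
cells are grouped with 8-connectivity (configurable to 4) and each group is
represented by its best cell under the cascade (species, individuals,
observations), with a final lexicographic (row, col) tie-break so the result
is deterministic. The same cascade orders hotspot acceptance: accepted
greedily, discarding any representative strictly closer than 450 m
("closer than" = strict inequality, centroid to centroid) to an accepted
hotspot.

The control ring consists of every cell whose square intersects the 500 m
circle around the hotspot centroid (square-intersects-circle test:
min-distance ≤ r ≤ max-corner-distance), ordered by the azimuth of the cell
centre clockwise from north; azimuth ties break by distance, then index.
The first ring cell that is farmland, non-perch, has ≤ 1 raptor observation
in the season, and sits ≥ 500 m from every already designated site (the
paired hotspot itself is exempt — it lies at exactly the ring radius)
becomes the control. A hotspot whose ring is exhausted is reported unpaired
rather than relaxing the radius, since the pairing distance is fixed by the
survey design. All hotspots enter the "taken" set before any control is
sought, so control placement never depends on the processing order of later
hotspots.

Designation from a previous season's data (the bootstrapping used when
surveys begin before the focal season ends) needs no special mode: any
usage table can be passed in.

## Survey aggregation and GLMs

Birds: abundance and richness averaged over the two seasonal point-count
visits (a visit that found no birds counts as zero, and richness ignores
zero-count placeholder rows). Small mammals: total captures over all
stations and nights; richness = distinct species captured. Amphibians:
totals over the five transects. Plants: richness is the union of the five
1 m² quadrats; similarity is the mean Jaccard index over the 10 quadrat
pairs. Two empty quadrats count as identical (Jaccard 1): they have equal
composition; the convention only matters for near-barren plots and is easy
to audit in the raw records. Plots with unusable records (e.g. a single
plant quadrat) are dropped with a logged id, which keeps the per-predictor
n transparent.

Each predictor is fitted alone: logit P(hotspot) = β₀ + β·x, by IRLS to a
relative log-likelihood tolerance of 1e-10 (statsmodels GLM under the
package's interface). Predictors are z-scored by default so the eight slopes
are comparable; raw-scale fitting is a flag. CI and p are Wald-based.
McFadden's R² = 1 − lnL/lnL₀; the companion "pseudo R²" is Nagelkerke's
rescaled Cox–Snell statistic, the conventional pairing in standard reporting
tools; both are always reported. Perfect separation is flagged
(`converged=False`) rather than raised — the slope is then unbounded and
its printed value meaningless.

A property worth knowing when interpreting simulation studies of this
estimator: the ML logistic slope carries the classic finite-sample
inflation, E[β̂] ≈ β·n/(n−p−2) (about +2.7% at n = 150 with an intercept
and one predictor, confirmed here by simulation). Wald CIs nevertheless
cover at ≈ 95%. Tests of strict mean-unbiasedness at Monte-Carlo precision
finer than this inflation will fail for any ML logistic fit; coverage, sign
recovery and calibration are the meaningful checks at survey-sized n.

## Persistence testing

Sites keep their exact 50 m cells across years ("measured on the same
plots"); later-year usage of unused cells is zero. W is the hotspot-group
rank sum (midranks under ties), related to the Mann-Whitney U by
W = U + n(n+1)/2. The exact null distribution is used when the smaller
group has ≤ 10 values and the pooled sample is tie-free; otherwise the
normal approximation with tie and continuity corrections. With sparse
later-year usage the data are mostly tied zeros, so the null p-distribution
is discrete and conservative (stochastically larger than uniform) — a
property of rank tests on tied counts, not a defect of the implementation.

## Synthetic worlds

The generator's job is to exercise the pipeline with known ground truth,
not to be a mechanistic flight model. Defaults describe a desk-scale
analogue of a mostly agricultural lowland: a 5 km × 5 km mosaic on a 100 m
parcel raster with target class shares farmland 0.46, forest 0.45, other
open 0.045, peatland 0.035, water 0.01, assigned by rank-thresholding
smoothed Gaussian fields (clustered blocks, realized shares within parcel
rounding of the targets). Twelve circular prey patches (radius 100 m,
quality boost 5) are placed on farmland with ≥ 1 km pairwise separation so
designated hotspots are geometrically separable.

Movement: four species × {3, 4, 4, 5} individuals; two species log at
5–10 min intervals, two at 10–60 min (soaring species charge their tags
better than perching species). Each individual alternates exponential nest
residence (mean 40 min) with foraging trips during a 06:00–20:00 activity
window over an 8-day season; the trip destination cell is drawn ∝
(quality)^α over farmland cells, reached as a straight commute at 10 m/s
with 30 m lateral path noise, followed by a 20–60 min dwell scattered 30 m
around the destination; all fixes get 10 m Gaussian GPS noise. α = 0 makes
destinations area-proportional (the movement null); α = 4 concentrates
≈ 90% of trips in patches.

Surveys: fauna counts are negative binomial (shape 5) with a geometric
rank-abundance split over each group's species pool; the mean is multiplied
by δ inside patches (δ = 1 is the survey null). Plant plots draw a local
pool from a 40-species regional pool — Poisson-sized around 10, larger
inside patches — and include each pool species in each quadrat with
probability 1 − turnover, with turnover higher inside patches, so patch
plots are both richer and more heterogeneous (lower mean pairwise Jaccard).

What the generator does *not* emulate: territoriality, weather- and
crop-cycle-driven nonstationarity, detectability differences between
observers or habitats, spatial autocorrelation of survey errors beyond the
patch structure, and GPS fix loss. Passing tests therefore demonstrate that
the pipeline recovers the planted structure under its own assumptions, not
that field data meet those assumptions.

Replicate studies in the tests use these desk-scale defaults (16
individuals, 8-day seasons, 12 patches); they finish in a few tenths of a
second per world, which is what makes 100–200-replicate calibration studies
part of the routine test suite.

## Known limitations

- No multi-predictor or mixed models, no spatial autocorrelation
  correction, no multiple-testing adjustment — the comparison design is one
  model per predictor by construction.
- Landcover input is GeoJSON polygons (plus an in-memory fast path for
  simulated parcel rasters); raster landcover files are not read directly.
- The local equirectangular projection is adequate for single-landscape
  studies; continental-scale inputs should be projected upstream.
- Designation treats one contiguous study area; disjoint areas should be
  run separately.
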