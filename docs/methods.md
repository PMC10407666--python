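# Methods

This note documents the statistical model, the design choices made where
the design was genuinely open, the synthetic-data generator, and the known
limitations of the package.

## Stability as a persistence probability

Ecological stability is treated as the probability that a landscape
maintains its ecosystem type under the prevailing environmental
conditions. The observable is binary: over the observation dates a pixel
either kept its land-cover class (steady, label 1) or held it at the first
date and lost it later (unsteady, label 0). Pixels that *enter* a class
after the first date are excluded (nodata) rather than counted as steady,
because a symmetric definition would conflate gains with persistence.
Only ecological classes — forest, grassland, wetland — are analysed;
desert and urban covers carry too little vegetation activity for a
stability signal and are dropped by legend tag.

Steady labels are then refined: a steady pixel whose multi-year NDVI *or*
GPP coefficient of variation (sample sd / mean over the available years)
exceeds `cv_max` is demoted to nodata. The rationale is that a pixel whose
vegetation activity swings wildly while its mapped class never changes is
more plausibly a land-cover classification error than a stable ecosystem;
demotion (rather than relabelling to unsteady) keeps classification error
out of the response variable entirely. `cv_max` defaults to 0.25 and is a
config knob; the threshold is a declared convention, not an estimate, and
lowering it can only shrink the steady set (a tested monotonicity
invariant).

## Landscape typing

Within each ecological class the steady pixels are partitioned by k-means
(10 restarts, seeded) on z-scored vegetation features — multi-year mean
NDVI and GPP by default. The canonical configuration analyses four
landscapes: forest (k=1), wetland (k=1), and grassland split into sparse
vs. high-coverage (k=2). Cluster ids are relabelled so the cluster mean of
the first feature (NDVI) increases with the id, which makes the map
invariant to initialization permutations; on a 1-D feature with k=2 the
partition provably matches the exhaustive optimal within-cluster-SS split,
and the test suite checks this against a brute-force oracle.

Unsteady pixels changed class, so the type map cannot label them; the
sampling stage attaches each one to the nearest cluster centroid of its
first-date class in the standardized feature space. For single-type
classes this reduces to the class's only landscape.

## The logistic stability model

Per landscape (and per factor year, see below) the steady/unsteady labels
are regressed on min–max-normalized factors,

    log(P/(1−P)) = β0 + Σ βi Zi,     ESI = P = expit(β0 + Σ βi Zi).

The fit is iteratively reweighted least squares with step-halving, so the
Bernoulli log-likelihood is non-decreasing across iterations (asserted in
tests); convergence when the max coefficient step or the log-likelihood
gain falls below `tol` (default 1e-8, `max_iter` 100). Standard errors
come from the observed information at the optimum. Complete or
quasi-complete separation makes the MLE diverge; it is flagged when any
|β| exceeds 15 on the Z scale (an odds ratio of e^15 across the unit
interval is not a finite optimum) and reported as an error naming the
offending factor. Collinear designs are rejected by a rank check.

Normalization scope: min/max are computed per landscape over its own
eligible pixels by default, so every fit sees covariates spanning [0, 1];
"global" (all eligible pixels) and "fixed" (externally supplied bounds,
e.g. a simulated scene's true ranges) are available. Fitted coefficients
and the achieved likelihood are invariant to this affine choice, but the
coefficient *values* are not — comparisons against planted truth therefore
use the fixed truth scope.

Because all Z lie in [0, 1], coefficient magnitudes are comparable across
factors and are reported as the factor contributions (sorted by |β|, ties
broken by factor code); odds ratios e^β are offered as an alternative
view. A separate model is fitted for each factor year against the single
persistence label, which is what makes contributions comparable over time;
the per-year fits share the same labels and differ only in the covariate
year.

ESI prediction is numerically stable for any linear predictor (log-space
logistic, no overflow) and clamps output to the open interval (0, 1) at
float resolution. A tested oracle property guarantees the mapped surface
equals the direct scalar evaluation of the logistic formula at every pixel
to ≤ 1e-12 relative error.

## Composite, classes, trend

Per year, the per-landscape ESI layers are combined by per-pixel maximum
(maximum value composite); argmax ties go to the lowest landscape id. The
multi-year surface averages the yearly composites ("MVC then mean", the
default); the alternative "mean then MVC" order is implemented and
recorded in the manifest, since either reading of a multi-year composite
is defensible. Classification uses breakpoints {0.2, 0.4, 0.6, 0.8} with
boundaries assigned to the upper class and the top interval closed — a
rule that must be fixed because the printed class ranges share endpoints.

The trend is the per-pixel OLS slope of annual ESI on calendar year (so
slope units are ESI per year), with a two-sided t-test at `alpha`
(default 0.05). With four epochs the test has 2 degrees of freedom —
acknowledged low power, i.e. the significance map is conservative. Pixels
with fewer than three valid years are nodata; a constant series has slope
0 and p = 1 by convention, and an exactly linear series has p = 0. The
empirical type-I error under an i.i.d. null is itself a tested quantity.

## Validation

Two checks are built in: the Pearson correlation between the multi-year
mean ESI and multi-year mean EVI (both "average state" products), and a
zonal comparison of mean ESI and class shares inside vs. outside reserve
polygons (cell-center-in-polygon rasterization; a center on the boundary
counts as inside). Zonal means provably weighted-average to the global
mean, which is asserted in tests.

## Synthetic scenes

The generator draws spatially autocorrelated covariate fields (Gaussian-
smoothed white noise with a configurable length-scale, default 5 pixels,
min–max scaled *exactly* to stated, field-plausible ranges for the eleven
factors: GDP, population density, precipitation, temperature, distances to
waterways/roads, aspect, elevation, slope, GPP, NDVI), a patchy land-cover
mosaic (grassland-dominated: 55 % grassland, 15 % forest, 10 % wetland,
15 % desert, 5 % urban), and a grassland coverage gradient (40 %
high-coverage). True stability probabilities come from planted logistic
coefficients per landscape (moderate magnitudes, |β| ≤ 2, so labels are
informative but never separable); realized labels are Bernoulli draws.
The emitted land-cover series keeps steady pixels fixed and changes each
unsteady pixel exactly once at a random interior date, so persistence
labelling must recover the realized labels with zero mismatches — a tested
construction consistency. NDVI/GPP follow class-specific means (the
sparse/high grassland gap is what typing must find) with small interannual
noise; EVI is `0.1 + 0.6·P + N(0, 0.05)`, a truthful positive control for
the greenness validation; one rectangular reserve is placed over the block
with the highest mean true probability, giving the reserve contrast a
known sign. Everything is reproducible from (config, seed).

What the scenes do **not** emulate: real terrain or climate structure,
correlation between covariate fields, spatially autocorrelated label noise,
classification error beyond the CV-refinement mechanism, or any actual
geography. Passing tests therefore demonstrate the correctness and
calibration of the machinery under a correctly specified model, not the
realism of any particular regional result.

## Problem sizes and numerical conventions

The canonical demo scene is 100×100 pixels (1 km cells) over four epochs
(2000/2005/2010/2015) — large enough that every landscape fits with
thousands of samples, small enough that a full pipeline run takes seconds.
Parameter-recovery checks use 250×250 scenes with 5000 samples per
landscape and 100 seeded replicates. Grids are float32 on disk (value
error < 1e-6 at ESI scale), float64 in memory. The analysis grid is the
land-cover grid of the first date; categorical layers resample
nearest-neighbour, continuous layers bilinear. Pixel convention:
(row, col), 0-based, cell-center semantics. Only north-up grids and a
shared CRS are supported; reprojection is out of scope.

## Limitations

* Persistence is binary and class-based: sub-pixel change, class-to-class
  transition structure and gains are not modelled.
* Samples are treated as independent; spatial autocorrelation inflates the
  effective sample size, so standard errors on real scenes are optimistic.
  Spatial thinning is noted as future work.
* The logistic model is unregularized, with no variable selection or
  interaction terms.
* Four time points give the trend test 2 df; only strong monotone changes
  reach significance.
* The CV refinement rule and its 0.25 default are conventions standing in
  for an unavailable error model of the land-cover product.
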