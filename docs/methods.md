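# Methods

This note documents the models and procedures topoflat implements, the
numerical choices made where the procedure left room, and what the synthetic
data generator does and does not emulate.

## Injection-site normalization

The source region's pial surface is modeled as a strip between a dorsal and
a ventral border polyline given in a common 3D reference space (mm). Both
polylines are smoothed by tricube-weighted local *linear* regression
(LOWESS) of each coordinate against cumulative arc length; the span (window
fraction) defaults to 0.5. The two borders are then resampled to a common
vertex count at equal arc-length fractions and the strip is triangulated by
splitting each quad between matched vertices into two triangles; the midline
is the pointwise midpoint of matched vertices, which makes it equidistant
from both borders in the resampled parameterization.

An injection's 3D coordinate is transposed to the surface by exact
point-to-triangle minimization over all triangles (region-based barycentric
projection; ties broken deterministically toward the lowest triangle index).
The normalized coordinates are

- dv = d_v / (d_v + d_d), where d_v and d_d are shortest *Euclidean*
  distances from the transposed point to the ventral and dorsal border
  polylines (0 = ventral, 1 = dorsal);
- rc = d_r / (d_r + d_c), where the foot of the shortest vector to the
  midline splits its arc length into d_r (to the rostral end) and d_c
  (0 = rostral, 1 = caudal).

Border distance is Euclidean, not geodesic along the surface; for the gently
curved strips this pipeline targets the difference is below the polyline
discretization error (the curved-strip recovery test bounds the total
coordinate error at 0.02, and in practice it is ~5e-4 at 80 border
vertices). Area assignment (A29 vs A30) compares the point's strip-dv with
the strip-dv of the nearest point on the A29/A30 boundary polyline.

## Age-normalized flatmap

Brains of different ages differ in size, so all measurements enter the
average flatmap as ratios within one animal:

1. each transverse extent s of a subdivision is divided by that animal's
   maximum extent of the same subdivision;
2. the animal's dorsoventral extent (number of sections containing the
   region × series spacing, overridable by a direct measurement) is divided
   by the same per-subdivision maximum;
3. the per-animal section profile is resampled onto smax equal dorsoventral
   rows — section centers at (j−0.5)/n, row centers at (i−0.5)/smax, linear
   interpolation, end values held at the edges. smax defaults to the
   maximum per-animal section count in the data set;
4. across animals: t̄_i (mean row extent), d̄v (mean normalized dorsoventral
   extent), T_i = t̄_i/d̄v, and the integer bins per row
   T_i^bin = round(T_i · smax), rounded half-up (ties away from zero).

Every bin is square in normalized units. The construction is exactly
invariant to multiplying any one animal's measurements (transverse and
dorsoventral alike) by a positive constant — the property the normalization
exists for, asserted by test.

The choice of *linear interpolation at row centers* for step 3 is a design
decision: a block assignment of sections to rows would be equally
defensible; interpolation was chosen because it is exact at matching grids
(n = smax) and smooth for young animals with few sections.

## Label mapping

Observations come per section, measured in µm from a subdivision-specific
reference border (proximal for presubiculum, distal for parasubiculum,
medial for the entorhinal cortices); distal-referenced measurements are
mirrored so all grids share a proximal/medial = 0 axis. Sections map to
rows by their center fraction of the animal's series.

- Plexus intervals: endpoints normalized by the section's transverse
  extent; bins whose centers fall in [start, end) receive the grade (1–3;
  the densest plexus of an experiment carries 3 by convention of the input
  data); overlapping intervals take the maximum.
- Fiber positions: assigned to half-open bins, last bin right-closed, value
  = count (total count is conserved).
- Rows inside the observed range without a mapped section (young animals
  have fewer sections than rows; damaged sections) are filled with the mean
  of the nearest observed rows above and below, matched across differing
  bin counts by normalized transverse position; edge rows copy their single
  neighbor.
- Per experiment, bins are normalized to the maximum-valued bin (all-zero
  maps are flagged empty and excluded from centers of mass). Pooling sums
  normalized maps and renormalizes; with subgroups, each subgroup is pooled
  and normalized first so every subgroup has equal weight regardless of
  size (replication-invariant, asserted by test).
- Center of mass of a field (superficial presubiculum; deep presubiculum +
  parasubiculum; medial + lateral entorhinal cortex, assembled
  proximal→distal / medial→lateral): mass-weighted mean of bin centers,
  dorsoventral coordinate 1−(i−0.5)/smax (1 = dorsal), transverse bin
  centers normalized by the row's assembled width so both coordinates lie
  in [0, 1].

Matching "the same location" across rows with different bin counts by
normalized transverse position is a design decision; the ragged grid admits
no unique answer, and left-aligned square bins make this the physical
adjacency for the dense embedding used in smoothing.

## Cluster analysis

Each normalized flatmap is smoothed with a 5×5 Gaussian kernel, σ = 1.5
bins, as normalized convolution on the dense left-aligned embedding: at
every bin the kernel weights are renormalized over the in-region support,
so out-of-region bins neither receive nor contribute mass and constant maps
are preserved. Pairwise Pearson correlations over the vectorized in-region
bins form a matrix whose rows are k-means clustered (squared-Euclidean, 50
restarts, fixed seed) for each candidate k; the within/between variance
ratio SSW/SSB is recorded per k.

The elbow is chosen as the smallest k whose ratio decrease when adding one
more cluster falls below 10% *of the curve's initial value*. Normalizing by
the curve scale rather than the current ratio keeps the criterion usable
once the ratio is near zero (with well-separated groups the ratio collapses
to ~0 at the true k, and any further relative decrease stays large while
the absolute decrease is negligible). The threshold is configurable and the
choice can be overridden outright — selecting k from a variance-ratio curve
is inherently judgment-laden.

## Topography regression

For each outcome (dorsoventral and transverse center of mass of each of the
three fields) a linear model

y ~ rc + dv + age + rc:dv + rc:age + dv:age

is fit by ordinary least squares on the experiments with a defined outcome
and age at or below the cutoff (default P19 — the study design has no
samples between P19 and the oldest animals, so the regression sample stops
there). Interaction predictors are products of the raw, uncentered
coordinates (0–1) and age in days. Backward elimination repeatedly removes
the interaction with the smallest |standardized β| among those not
significant (two-sided t, p ≥ α, default α = 0.05) and refits, until all
remaining interactions are significant or none remain; main effects are
never removed, and the full elimination trace is returned. Consequences of
the convention: α = 0 eliminates every interaction (main-effects model),
α = 1 eliminates none (full model).

Coefficients are reported unstandardized with 95% confidence intervals, t,
p, and standardized β = b·sd(x)/sd(y) computed on the estimation sample
(standardization changes neither t nor p, asserted by test). Diagnostics:
pairwise Pearson correlations among the main predictors with a |r| < 0.70
pass criterion, VIF = 1/(1−R²) per retained term from auxiliary
regressions, and standardized residual/prediction summaries with histogram
and normal-quantile exports. A rank-deficient design raises an error naming
the aliased terms. The age-dichotomization check replaces age by the
indicator age ≥ 7 days (younger vs older than one week).

## Synthetic studies

The generator emulates the statistical structure the analysis assumes, not
the histology:

- **Surface**: a strip of length 8 mm and width 2 mm, flat or isometrically
  bent around a cylinder (curvature default 0.15/mm), with injections at
  known parametric (rc, dv) displaced 0.3 mm off-surface along the normal.
- **Animals**: one per experiment; dorsoventral extent 2000 µm at birth
  growing linearly by 8%/day, sectioned at 200 µm; per-subdivision
  transverse profiles are smooth and unimodal (0.55 + 0.45·sin πu) with
  multiplicative lognormal noise (σ = 0.1). Ages are drawn with the
  empirical age-group proportions of the emulated study design (33 : 52 : 20
  for P1–6 : P7–13 : P14–19).
- **Topography**: terminal dorsoventral center 0.9 − 0.5·rc (caudal
  injections project ventrally) and transverse center 0.15 + 0.6·dv
  (dorsal injections project distally/laterally); per-experiment center
  jitter σ = 0.03; terminal spread σ = 0.08 flatmap units. All slopes are
  generator choices reflecting the qualitative gradient directions of the
  emulated system, not measured values.
- **Density by age**: expected fiber count 2·e^(0.35·age), capped at 400 —
  a handful of single fibers in the first days, plexus-scale labeling from
  P12 on. At P12 or older the generator emits graded plexus intervals
  (grade 3 at the modal rows, 1–2 at the flanks, derived by thresholding
  the dorsoventral Gaussian weight) instead of fiber lists.

Everything is driven by one `numpy` generator seeded from the study seed;
identical (config, seed) pairs produce byte-identical output files.

What the generator does *not* emulate: tissue deformation and cutting-angle
variation, cytoarchitectonic delineation error, tracer uptake variability,
multi-injection animals, spatially correlated measurement error, and any
labeling outside the five modeled subdivisions. Passing recovery tests
therefore demonstrate the pipeline's correctness and statistical power
under the assumed generative structure, not robustness to histological
artifacts.

## Problem sizes and tolerances

The test suite and the acceptance script use 100-replicate batteries for
simulation-based checks (sign/magnitude recovery, null calibrations) at the
emulated study size of ~105 experiments, 80-vertex border polylines, and
flatmaps of ~25–30 rows; these sizes hold every Monte-Carlo check
comfortably while keeping a full run in the minutes range. Geometric
identities are asserted at 1e-6 to 1e-9; the least-squares implementation is
checked against a direct normal-equations solution at 1e-8; recovery
tolerances (sign in ≥95% of replicates, magnitude within ±30% in ≥90%)
reflect the sampling noise of ~105-experiment studies with the default
spread and jitter.

## Known limitations

- Geodesic border distances are approximated by Euclidean ones (see above).
- The flatmap's ragged-grid smoothing assumes left-aligned physical
  adjacency; target regions whose rows align at the distal border would
  need a mirrored embedding.
- Backward elimination inherits the usual caveats of stepwise selection;
  the elimination trace is exposed so final models can be reconciled
  against alternatives.
- k-means on correlation-matrix rows treats each experiment's correlation
  profile as a feature vector; it does not model uncertainty in the
  correlations.
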