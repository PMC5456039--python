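# Methods

`arstrack` implements the analysis chain used to study fine-scale foraging
behaviour of a colonial, central-place foraging seabird from GPS tracking:
detect area-restricted search (ARS) along each at-sea day, attach gridded
oceanographic covariates to every location, model ARS vs non-ARS per
bird-day with tree ensembles, and compare behaviour across biological
groups with permutation statistics. A synthetic-study generator with
recorded ground truth makes the whole chain testable without field data.

## Track processing

Raw fixes (lon/lat, 10–100 s cadence) are projected to planar metres with a
local azimuthal-equidistant projection centred on the colony. Within 300 km
of the centre, planar distances agree with great-circle distances to well
under 0.1%, which is all downstream steps require; the projection inverts
exactly on the sphere.

Cleaning and structuring:

- **Speed filter.** Fixes implying > 90 km/h flight are removed
  iteratively: the later fix of the first violating pair is dropped and
  speeds recomputed until none remain.
- **Trip splitting.** A trip is a maximal run of fixes beyond a colony
  buffer (default 1 km — the island is ~0.5 km², and the buffer is
  configurable since the at-colony criterion is a judgement call), extended
  by the fix immediately before departure and after return.
- **Night rest / bird-days.** A rest bout is a maximal night-time run
  (local solar 20:00–05:00 at the colony longitude) with windowed speed
  < 2 km/h lasting ≥ 1 h. Speed here is measured over a trailing 4-fix
  displacement rather than fix-to-fix: at 10–100 s cadence, instantaneous
  speeds of a drifting bird are dominated by GPS jitter (~10 m), which the
  window averages out. Segments between removed bouts are the bird-days;
  days with fewer than 50 interpolated locations are dropped.
- **100-m interpolation.** Each bird-day is resampled at 100-m arc-length
  steps along its polyline (timestamps linearly interpolated within
  segments; the final step may be shorter). Spacing is defined along the
  path, so chords across corners are shorter than 100 m — this matches the
  usual convention for path-based resampling and is what first-passage-time
  analysis expects.

## First-passage time and ARS scales

FPT at a location is the time to cross a circle of radius r centred there,
travelling forward plus backward along the track. Exit instants are found
by exact segment–circle intersection with linear time interpolation, so FPT
is exact on the polyline (verified against a 1-cm dense-resampling brute
force to < 1e-6 relative). Locations whose circle is never exited before a
track end are undefined at that radius and excluded.

The candidate radius grid runs from 10 m (≈ GPS accuracy) to half the mean
colony distance, capped at 35 km, in 10-m increments; desk-scale runs
coarsen the step (50–100 m), which does not move the detected peaks beyond
the grid resolution. The variance of log(FPT) across locations is computed
at every radius where ≥ 50% of locations are defined, smoothed with a
5-bin moving average, and its local maxima (prominence ≥ 5% of the curve
range, with an absolute floor of 0.01 so featureless curves yield nothing)
are the day's ARS scales. Scales > 8 km are treated as mesoscale search
and excluded from fine-scale analysis; the smallest remaining scale is the
day's "small-scale ARS".

## Penalized-contrast segmentation

Per day, log(FPT) at the smallest scale is partitioned into K homogeneous
segments by dynamic programming over the within-segment sum of squared
deviations — exact for every K, verified against exhaustive enumeration.
K ∈ [2, 20] with a minimum segment length of 5 locations. K is chosen by a
penalized rule on the contrast decrease: J(K) is scaled to [0, 1] over
K = 1..Kmax, successive decreases are multiplied by (Kmax − 1) — so a
featureless series scores ≈ 1 — and the largest K whose scaled decrease
exceeds S = 0.75 is chosen (Kmin when none does). The threshold, Kmin/Kmax
and the minimum length are all exposed; the published description of the
method leaves these constants open, and this scaling is the one used by
the standard animal-movement implementation of the criterion.

Segments whose mean log FPT strictly exceeds the day mean are ARS
(ties are non-ARS); adjacent ARS segments merge into zones. Day metrics:
zone count, ARS duration, path distance inside ARS, mean colony distance,
and the circular mean of colony-to-ARS bearings.

## Environmental annotation

Eleven covariates: bathymetry, chlorophyll-a (8-day, monthly), mixed layer
depth, SSHA, SST (daily, 8-day, monthly), surface-current velocity, wind
speed, and distance to the nearest SST front. Each gridded variable is
sampled at its native resolution by bilinear interpolation (exact at grid
nodes; missing if any neighbour cell is masked or the point is out of
bounds). Stacked rasters are matched in time to the nearest layer within
half the product cadence (6 h wind, 12 h daily, 4 d 8-day, ~15 d monthly;
earlier layer on ties). Distance-to-front is the great-circle distance to
the centre of the nearest cell whose front probability exceeds a threshold
(default: any positive probability; the cut-off is configurable because
the upstream front product does not prescribe one).

## Habitat models

Each bird-day with both response classes gets its own ensemble of Gini
decision trees (default 1000): every tree trains on an independent random
two-thirds of the day's locations drawn **without** replacement and is
validated on its held-out third; 3 = floor(√11) candidate predictors per
split; trees grow to purity (minimum leaf size 1, the convention of the R
`randomForest` classifier this mirrors; the leaf size is exposed).
Sensitivity/specificity/accuracy are held-out rates averaged over trees.
Raw importance is the impurity decrease summed per variable and averaged
over trees, standardized per day to sum to 100%.

Population-level importance uses a stratified bootstrap: each of 1000
iterations draws one day per trip per bird (one day per bird for
within-period summaries) and averages the day importances; the summary is
the mean and SD of the iteration means. Because each day sums to 100%,
every iteration mean does too — a useful internal invariant.

Marginal effects come from partial-dependence curves (predicted ARS
probability with one variable forced across its observed quantile grid),
pooled across days on a common grid and smoothed with a GCV-penalized
smoothing spline plus a pointwise normal-approximation 95% band.

Spatial autocorrelation between consecutive 100-m locations is deliberately
not corrected, matching the analysis this package reproduces; treat per-day
validation rates as optimistic for truly independent locations.

Two properties of impurity importance worth knowing when reading per-day
profiles: importances are standardized within a day, so they are relative,
not absolute, effect sizes; and under a permuted (uninformative) response
the importance share splits evenly only across predictors with comparable
within-day variation — a covariate that is nearly constant over a day's
footprint is structurally down-weighted. The null-calibration check
therefore uses exchangeable predictors.

## Behaviour statistics

Trip descriptors (duration, total distance, maximum colony distance,
smallest/largest ARS scale) and small-scale ARS characteristics are
z-scored (angles enter as sin/cos pairs — a circular quantity treated
linearly would wrap), converted to Euclidean distances, and ordinated with
nonmetric MDS (classical-scaling initialisation plus random restarts;
Kruskal stress-1). Group location is tested with perMANOVA
(distance-based pseudo-F; p = (1 + #{F* ≥ F}) / (n_perm + 1), 10 000
permutations, exact enumeration available for tiny designs) and group
spread with a multivariate dispersion test: distances to group centroids in
principal-coordinate space (negative-eigenvalue axes subtracted, the
standard correction for non-Euclidean dissimilarities), one-way ANOVA F,
permutation of model residuals. Centroids (means) rather than spatial
medians are used, matching the Levene-style construction. Trip-type
proportions use Pearson chi-squared without continuity correction.

## Synthetic studies and what they do (not) show

The generator emulates a realistic colony tracking campaign: 135 birds by
default,
1–9 trips per bird (truncated geometric, mean ≈ 2.2), day mix 67/30/3%
for 1/2/3-day trips, fixes every 10/33/50/100 s, commuting at ~10 m/s with
small heading noise, ARS bouts as centre-attracted correlated random walks
inside patches of known radius (nested scales by embedding small bouts in a
larger search region), overnight drift ≤ 0.5 km/h on multi-day trips, and
10-m Gaussian GPS jitter. Trip ranges default to 20–80 km. Driver fields
(SSHA < 0 m and velocity 0.05–0.1 m/s by default) equal their band midpoint
inside every smallest-scale patch footprint and stay outside the band
elsewhere; the other fields are smooth random surfaces uncorrelated with
behaviour; all fields stay inside the observed ranges of their real
counterparts. Driver rasters are generated at 0.005° so that a ~1-km patch
spans several cells — at the native 0.33° resolution of a real
surface-current product a patch-scale band would be unrepresentable — while
non-driver fields use 0.02° grids.

What passing tests show: the FPT/segmentation machinery recovers known
scales and bouts; the habitat model recovers known drivers; the statistics
are calibrated. What they do not show: performance under real oceanographic
spatial structure (smooth fields here are isotropic Gaussian surfaces),
under tag failure/irregular sampling, or under behavioural states the
generator lacks (e.g. drift foraging, rafting near the colony).

## Problem sizes used in validation

Validation runs are sized for a desk machine and state their sizes
explicitly: FPT oracle on 20 twelve-vertex tracks; scale recovery on 100
single-patch days (radius step 50 m, r_max 8 km); segmentation exactness on
50 series of length 30 (Kmax 4); labelling accuracy on 100 days; driver
recovery on 20 replicate studies of 20 birds with 200-tree forests and
200 bootstrap iterations; importance-null calibration over 50 label
permutations; permutation-test calibration over 500 null replicates at
n_perm = 999. The defaults of the library itself remain the full-scale
values (1000 trees, 1000 iterations, 10 000 permutations, 10-m radius
step).

## Known limitations

- On non-final days of multi-day trips the bird fills the time until dusk
  with commute-like transit (fast, nearly straight, folded back inside the
  trip range). Slow tortuous loitering was rejected for this filler: FPT
  rightly classifies such movement as search, which would blur the
  patch/non-patch ground truth the generator is supposed to pin down.
- FPT peak radii overestimate the generating patch radius by up to ~2×
  (a known property of variance-of-log-FPT scale selection); recovery is
  therefore scored within a factor of two.
- `rmax_from_data` uses the mean colony distance of the supplied locations;
  on multi-modal trips this can under- or over-shoot the interesting range.
- The dispersion test permutes residuals under the reduced (equal-spread)
  model; with tiny, very unbalanced groups its size can drift a few points
  from nominal.
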