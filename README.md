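# arstrack

Area-restricted-search detection and habitat modelling for GPS tracks of
central-place foraging seabirds.

Breeding seabirds commute from a colony to feed at sea, and the tortuous,
localized movement they show over prey patches — *area-restricted search*
(ARS) — is a usable proxy for foraging. This package implements the full
analysis chain for such tracking studies, for movement ecologists who want
a tested, scriptable alternative to ad-hoc R pipelines:

1. **Track processing** — speed filtering (> 90 km/h), colony-buffer trip
   splitting, overnight-rest removal, bird-day splitting, and linear
   interpolation to 100-m spacing along the path.
2. **First-passage time (FPT)** — for each location, the time t(r) to cross
   a circle of radius r travelling forward + backward along the track. The
   local maxima of Var[log t(r)] over r identify the spatial scales of
   search; scales ≤ 8 km are "small-scale ARS".
3. **Segmentation** — per day, log FPT at the smallest scale is cut into
   K ∈ [2, 20] homogeneous segments by exact dynamic programming on the
   within-segment contrast J(K), with K chosen by a penalized threshold on
   the normalized decrease of J; segments with above-average log FPT are ARS.
4. **Environmental annotation** — 11 oceanographic covariates (bathymetry,
   Chl-a ×2, mixed layer depth, SSHA, SST ×3, current velocity, wind speed,
   distance to nearest front) sampled per location by bilinear interpolation
   with temporal matching.
5. **Habitat models** — per bird-day, an ensemble of Gini decision trees
   (2/3 subsample per tree without replacement, held-out validation,
   mtry = ⌊√11⌋ = 3); Gini importance standardized to 100% per day, then a
   stratified bootstrap (one day per trip per bird, 1000 iterations) gives
   population-level importance G̅_j ± SD; partial-dependence curves with a
   penalized-spline smooth give marginal effects.
6. **Behaviour statistics** — NMDS ordination (Kruskal stress-1), perMANOVA
   (pseudo-F, 10 000 permutations), multivariate dispersion (Levene-type,
   residual permutation), and χ² tests on trip-type proportions.

A seeded synthetic-study generator (`arstrack.simulate`) produces tracks,
metadata and environmental rasters with recorded ground truth — patch
centres/radii, bout intervals, and designated "driver" variables active only
inside patches — so every stage is verifiable end-to-end without any data
download. See `docs/methods.md` for the model details and assumptions.

## Worked example

```python
import arstrack as a

# a small synthetic colony study: 12 birds, 1-3 trips each
cfg = a.SimConfig(seed=4, n_birds=12, trips_per_bird_range=(1, 3),
                  trip_range_km=(15, 30))
bundle = a.simulate_study(cfg)          # tracks + 12 rasters + ground truth

res = a.run_study(bundle, radius_step_m=50, r_max_m=8000,
                  n_trees=200, n_boot=200, seed=1)

print(res.ars_metrics[["n_scales", "n_zones", "duration_h",
                       "distance_km"]].describe().loc[["mean", "min", "max"]])
print(res.bootstrap.frame().sort_values("mean", ascending=False).head(4))
```

Output (this exact script, seed 4; 21 bird-days detected):

```
      n_scales   n_zones  duration_h  distance_km
mean  1.285714  1.666667    1.239027    14.342174
min   1.000000  1.000000    0.919587     9.901847
max   2.000000  2.000000    1.641800    19.149865
            variable       mean        sd
9           velocity  13.500339  0.753063
5               ssha  13.015858  0.494314
4  mixed_layer_depth  12.938597  0.742085
3  distance_to_front  10.163024  0.522983
```

Reading it: each simulated bird-day shows 1–2 detected search scales with
ARS totalling ~1.2 h and ~14 km of path, and across the stratified
bootstrap the two designated driver fields (current velocity and SSHA)
carry the largest standardized Gini importance. The uninformative smooth
fields sit close behind at this small study size — spatially compact ARS
patches partially confound any smooth field within a single day, and the
margin widens as bird-days accumulate (the validation runs at 20 birds
separate the drivers cleanly). On real data the
same `run_study` call takes a
directory loaded with `a.load_study(path)` whose tracks/rasters follow the
documented CSV layouts.

A CLI mirrors the main entry points:

```bash
arstrack simulate --seed 4 --n-birds 6 --out study/
arstrack behavior-stats --metrics trips.csv --factor sampling_period --nperm 10000 --seed 42
arstrack rf-habitat --design design.csv --ntrees 1000 --mtry 3 --niter 1000 --seed 42
```

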