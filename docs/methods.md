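# Methods

## Model

The package maps population through a two-step dasymetric procedure.  Step 1
fits, for each census year independently, a random-forest regression of
unit-level log population density on zonal means of gridded covariates, and
evaluates it per pixel to obtain a prediction-density weighting layer.  Step
2 spreads each unit's census count over its pixels proportionally to that
layer, which conserves unit totals by construction.  The model's central
assumptions are:

* population density at the unit level is a smooth (but unknown) function of
  the covariates, so unpruned bagged trees with all covariates candidate at
  each split can approximate it without parametric form;
* the density–covariate relationship may change between census years
  (rapidly urbanizing regions), so each year gets its own forest, and maps
  are only comparable because all years share one fixed target tessellation
  onto which counts are harmonized by intersection-area weighting;
* within a unit, relative pixel weights carry all the spatial information;
  any constant multiplicative bias in the weighting layer cancels in the
  redistribution, which is why no bias correction (smearing) is applied to
  the exponential back-transform of the log-scale forest predictions.

The response is natural-log density in people per usable pixel,
`ln(count / pixel_count)`.  A pixel is usable when every covariate layer
holds data there; zones with zero count or no usable pixel are excluded from
fitting (log undefined) but still receive predictions.  Zonal predictor
summaries are means only.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_estimators` | 500 | trees per forest; bagging is the only regularization |
| `min_samples_leaf` | 1 | unpruned trees, single-observation leaves |
| `max_features` | all | covariates considered at every split |
| `min_rows` | 20 | refuse to fit a forest on fewer census units |
| containment share | 0.999 | source polygon counted as inside one target when ≥ 99.9 % of its area falls there (absorbs digitized-boundary slivers) |
| pixel size | 100 m | working grid; one pixel = one hectare, so ppp = pph |
| conservation gate | 1e-6 relative | per-zone redistribution residual above this fails a run (measured ~1e-15) |

Permutation importance permutes a covariate among each tree's out-of-bag
cases, recomputes the OOB MSE and reports `100·(MSE_perm − MSE_orig)/MSE_orig`
averaged over `n_repeats` (default 5) shuffles.  The raw percent increase is
reported without normalizing by the spread of per-tree differences; an
identity-permutation hook exists solely to verify the bookkeeping returns
exactly zero.

The forest is implemented as an explicit bagged ensemble of scikit-learn
decision trees with package-controlled bootstrap sampling, because the
OOB machinery (per-tree OOB index sets for honest error and importance) is
first-class here and must be exactly reproducible given a seed.

## Covariates

Signed distance to the built edge is center-to-center Euclidean on the
projected grid: a built cell carries minus its distance to the nearest
non-built cell center, a non-built cell plus its distance to the nearest
built cell center.  Magnitudes are therefore always ≥ one pixel and zero
never occurs; the sign partition equals the input mask exactly, which makes
the transform testable against an all-pairs brute-force oracle.  The stack
for year index *t* contains the static layers (elevation, Horn 3×3 slope in
degrees with edge replication, distance to rasterized water features), the
year's lights composite (cellwise mean when two satellites cover one year;
a nodata cell in any input stays nodata), and one signed built-distance
layer for the current and each preceding year, oldest first.  Nodata in any
layer marks a pixel unusable rather than fabricating a value.

## Geometry and grids

All computation happens in one projected CRS with meter units on square
pixels; row 0 is the northernmost row and extents are half-open.
Rasterization assigns each pixel the polygon containing its center, ties on
shared boundaries going to the lowest unit id (order-independent and
deterministic).  Alignment resamples to the intersection extent at the
finest pixel size — nearest-neighbor for categorical layers, bilinear with
conservative nodata propagation for continuous ones.

Persistence uses plain-text formats throughout: ESRI ASCII grids with a JSON
sidecar carrying the CRS id and dtype (integer rasters round-trip exactly,
floats to double precision), GeoJSON zone sets, CSV census tables.  The
geographic export maps the local meter grid to a lon/lat grid through a
tangent-plane (equirectangular) approximation around a reference point, with
an angular step equal to the geometric mean of the source pixel's angular
extents.  People-per-pixel is reprojected by *forward nearest binning* —
every source pixel's mass lands in the target cell containing its center —
because inverse nearest sampling between incommensurate grids aliases rows
and columns and was measured to drift totals by ~2 %; forward binning
conserves the grand total exactly.  People-per-hectare, an intensity, uses
ordinary inverse nearest sampling.  The working-projection product remains
the mass-true reference; the report records both totals.

## Synthetic study region

The generator emulates the statistical structure the model assumes, not any
real geography: a smoothed Gaussian random field for terrain; monotone
random-walk rivers; built extents grown by radial dilation from
low-elevation seed points (non-decreasing over years by construction);
lights equal to a DMSP-like ceiling times the local built fraction plus
noise; and true log density

    ln ppp = α − β_t · d_km + γ · (lights / lights_max) + ε,   ε ~ N(0, σ²)

with α = 3 (≈ 20 people per pixel at the built edge), β = 1.5 per km in the
`static` regime or (2.4, 1.5, 0.8) per year in `timevary`, γ = 0.8 and
σ = 0.2.  The distance-decay term dominates by design, so the signed
built-edge distance is the generator's strongest covariate and density is
monotone decreasing in it conditional on lights — the oracle used by the
model tests.  Surfaces are scaled per coarse zone so zone totals are
integers; census tables are exact zonal sums, so conservation can be checked
to float precision end to end.

Tessellations are Voronoi cells of k-means centers of (a 10 000-pixel sample
of) pixel centers — irregular, administrative-looking zones with controlled
counts.  Fine (validation) cells are grouped into coarse (model) zones by a
second k-means on their centers, so nesting is exact at both the polygon and
raster level.  The default world is 200×200 pixels at 100 m, three census
years, 100 coarse and 400 fine zones — sized so the complete pipeline runs
in a few seconds and the whole test suite in about a minute on one CPU.

What the generator does **not** emulate: classification error in built
extents, sensor saturation and blooming in lights, unit-level heterogeneity
beyond the pixel-iid noise term, boundary changes between census years, and
coastal slivers.  Consequently the synthetic out-of-bag variance explained
(~0.99) is higher than what heterogeneous real census data yield — zone-mean
aggregation averages the pixel noise away — and passing tests demonstrate
correctness of the machinery and recoverability of a known law, not
real-world accuracy.

## Temporal comparison

The argument for fitting years independently is tested by comparing, in each
regime, per-year forests against a single forest pooled over all years on a
common covariate set (static layers, lights, current-year built distance).
Agreement with the known surface is measured by Pearson correlation **on the
log-density scale** of the predicted weighting layer.  The log scale is the
model's own response scale and the scale on which a year-varying decay
coefficient distorts predictions across the whole domain; correlation on the
people-per-pixel scale is dominated by a handful of urban-core pixels, and
the per-zone count conditioning of the redistribution cancels most of a
pooled model's misfit there, masking the effect.  Under the year-varying law
the per-year strategy wins on every seed (≈ 0.98 vs ≈ 0.95, five seeds);
under the static law the two are statistically indistinguishable — pooling
is adequate exactly when the law is stable.

## Validation metrics

RMSE, MAE and MAD (median absolute error) are computed on per-unit counts;
%RMSE divides by the mean observed count per unit (a grand-total denominator
is available behind a switch); RMSE/Area is the RMSE of per-unit density
errors, so the counts-scale RMSE/Area equals the densities-scale RMSE — a
structural identity asserted in the tests.  MAD is the median of absolute
errors, not the median-centered deviation of errors: it sits alongside MAE
as a robust error summary for highly skewed count distributions.

## Numerical choices and degenerate inputs

* Harmonized counts stay real-valued; conservation takes priority over
  integrality.  Mass falling outside every target is tracked as
  `unallocated`, never silently dropped.
* Zones whose usable weights sum to zero fall back to uniform allocation
  over all their pixels (census mass is never lost); usable zero-weight
  pixels inside a live zone receive exactly zero people; pixels whose
  weight is nodata receive zero people and their share moves to the zone's
  usable pixels.
* A constant response fits without error but reports variance explained as
  undefined (NaN).  All-built or all-non-built masks refuse the distance
  transform (the edge is undefined).  DEMs smaller than 3×3 refuse the slope
  estimator.
* All randomness flows from explicit seeds: world generation from the
  config seed, each year's forest from `seed + year_index`, permutation
  importance from its own seed.  Identical configuration and seeds
  reproduce every number bit-for-bit.

## Known limitations

Single in-memory grids only (no tiling for continental rasters); a single
configured projection pair rather than general CRS transforms; zonal
predictor summaries limited to means; no spatial cross-validation,
hyperparameter tuning, growth-rate adjustment to external national totals,
or temporal interpolation between census years.
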