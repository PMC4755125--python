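# popgrid

Temporally-comparable, random-forest dasymetric population mapping: from
census counts on administrative polygons plus covariate rasters to
count-preserving ~100 m gridded population surfaces for multiple census
years, with out-of-bag model diagnostics and a validation metric suite.

## The problem and the method

Census data report *how many* people live in each administrative unit but not
*where* inside it.  Gridded population surfaces answer the "where" by
redistributing each unit's count across fine grid cells — the denominators
behind population-at-risk estimates in epidemiology, disaster response and
urban planning.  When a region urbanizes rapidly, maps for different census
years are only comparable if they are built over identical unit boundaries,
from covariates that are either time-invariant or available per year, and
with a model refitted for each year (because the relationship between
population density and urban form itself changes over time).

`popgrid` implements this as a two-step pipeline:

**Step 1 — density model.**  For each census year *t*, a random-forest
regression predicts unit-level log population density

&nbsp;&nbsp;&nbsp;&nbsp;ln *D<sub>i</sub>* = ln(count<sub>i</sub> / pixels<sub>i</sub>) ≈ *f<sub>t</sub>*(x̄<sub>i</sub>)

from zonal means x̄<sub>i</sub> of the covariate stack: elevation, Horn
slope, distance to water, nighttime lights, and a **signed distance to the
built-land edge** (negative inside built areas, positive outside) for year
*t and every preceding year* — the lagged layers encode settlement history.
The forest follows the classic bagging recipe: 500 unpruned trees,
single-observation terminal nodes, all covariates candidate at every split.
Out-of-bag (OOB) predictions give an honest mean-squared error on the log
scale, the variance explained, and Breiman permutation importance (percent
increase in OOB MSE).  Applying *f<sub>t</sub>* per pixel and exponentiating
yields the prediction-density weighting layer P<sub>d</sub>.

**Step 2 — dasymetric redistribution.**  Each unit's census count is spread
over its pixels proportionally to P<sub>d</sub>:

&nbsp;&nbsp;&nbsp;&nbsp;ppp(p) = count(z) · w(p) / Σ<sub>q∈z</sub> w(q)

so every unit total is conserved exactly — the pipeline's central invariant,
enforced to 1e-6 relative (measured ~1e-15).  Products are people-per-pixel
(ppp) and people-per-hectare (pph) rasters, optionally exported to a
geographic (lon/lat) grid.

Validation aggregates the surface to a finer tessellation and compares with
observed counts via RMSE, RMSE/Area (the RMSE of per-unit densities), %RMSE,
MAE and the median absolute error (MAD), on both the counts and densities
scales.

A **synthetic world generator** supplies every input — terrain, rivers,
monotonically growing built extents, lights, nested coarse/fine census
tessellations, and a per-pixel ground-truth population drawn from a known
density law — so the whole pipeline is testable without any restricted
census or satellite data.

## Worked example

```python
from popgrid import WorldConfig, generate_world
from popgrid.pipeline import run_pipeline

world = generate_world(WorldConfig(seed=42))   # 3 years, 100 zones, 200x200 px
result = run_pipeline(world, seed=42)
for year, res in result.years.items():
    m = res.metrics["counts"]
    print(f"{year}: OOB R2={res.model.oob_variance_explained_:.3f} "
          f"OOB MSE(log)={res.model.oob_mse_:.3f} "
          f"max|resid|={res.max_conservation_residual:.2e} "
          f"%RMSE={m.pct_rmse:.1f} corr(true)={res.pixel_corr_true:.3f}")
```

prints

```
1990: OOB R2=0.994 OOB MSE(log)=0.049 max|resid|=1.77e-15 %RMSE=43.9 corr(true)=0.885
2000: OOB R2=0.996 OOB MSE(log)=0.036 max|resid|=1.98e-15 %RMSE=53.9 corr(true)=0.858
2010: OOB R2=0.995 OOB MSE(log)=0.044 max|resid|=2.13e-15 %RMSE=67.7 corr(true)=0.869
```

Reading the numbers: `OOB R2` is the out-of-bag variance explained of each
year's density forest at the census-unit level; `OOB MSE(log)` the matching
error on log density; `max|resid|` the worst per-zone relative gap between
the redistributed pixel sums and the census counts (float-precision zero,
i.e. the counts are conserved); `%RMSE` the validation RMSE against the
finer census tessellation as a percent of the mean observed count; and
`corr(true)` the pixel-level Pearson correlation between the product and the
generator's known true surface.

The same run is available from a shell:

```bash
popgrid run-all --seed 42 --out runs/demo          # whole pipeline + report
popgrid synth --seed 42 --out runs/demo            # or stage by stage:
popgrid harmonize --out runs/demo
popgrid covariates --out runs/demo
popgrid fit --seed 42 --out runs/demo
popgrid predict --out runs/demo
popgrid redistribute --out runs/demo
popgrid validate --out runs/demo
```

Stage outputs (harmonized counts, zonal tables, weighting layers,
`SYN_ppp_<year>.asc` / `SYN_pph_<year>.asc` products, model cards and
`run_report.json`) accumulate in the `--out` directory.

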