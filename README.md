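# socmap

Spatially explicit mapping of forest soil organic carbon (SOC) stocks with
quantile regression forests, for forest-carbon accounting in mountainous
terrain where inventory plots are sparse, clustered, and biased toward
accessible ground.

The package implements the full digital-soil-mapping workflow around a
clustered national-forest-inventory plot table (topsoil SOC density,
t C ha⁻¹, 0–30 cm):

- **scorpan covariate construction** — terrain derivatives from a DEM
  (Horn slope, topographic position index, topographic wetness index via D8
  routing after priority-flood sink filling, a horizon-based wind-exposure
  index), forest-edge distance, and a Naismith-style least-cost walking-time
  surface from the road network as a disturbance proxy.
- **Quantile regression forest (QRF)** — a CART ensemble whose leaves retain
  their in-bag training observations, so each prediction cell yields a full
  conditional distribution via Meinshausen weights: for every tree, mass
  `1/(leaf size · n_trees)` on each in-bag observation sharing the cell's
  leaf. The conditional mean is the SOC map; the conditional SD is the
  per-cell model uncertainty. Permutation importance (mean decrease
  accuracy) and partial dependence come from the same out-of-bag machinery.
- **Leave-location-out spatial cross-validation** — folds are groups of
  whole plot clusters, never splitting a cluster, so spatially correlated
  noise shared within a cluster cannot leak from training to test. Model
  skill is the pooled out-of-fold RMSE
  `sqrt(Σ(yᵢ − ŷᵢ)²/n)` and R².
- **Uncertainty maps** — sampling-design *sensitivity* as the per-cell SD of
  the 10 prediction maps refitted on the spatial-CV training sets, and the
  combined relative error
  `percent error = 100 · (model SD + sensitivity SD) / mean`.
- **Stock totals** — total stock in Mt C as Σ(cell mean × cell area), with
  the combined per-cell SE aggregated under both an independence
  (root-sum-of-squares) and a fully correlated (plain sum) model; sums use
  compensated summation in fixed order so totals re-derived from the
  written rasters match bit for bit.
- **Area of applicability (AOA)** — per-cell dissimilarity index (DI): the
  minimum importance-weighted standardized distance to any training plot in
  predictor space, normalized by the mean pairwise training distance; cells
  whose DI exceeds the 0.95 quantile of the cross-validated training DIs
  fall outside the AOA and their predictions are flagged untrustworthy.
- **Residual variograms** — empirical semivariance of the CV residuals in
  regular distance bins with a 99-permutation Monte-Carlo envelope as the
  no-autocorrelation null.
- **Map comparison** — block-mean aggregation to coarser reference grids and
  RMSE/bias overall and by elevation zone (<1000, 1000–3000, >3000 m).
- **Synthetic study area** — a fully known test bed: fractal DEM, derived
  and simulated covariates, elevation-banded soil/lithology maps, SOC truth
  from a known linear covariate model plus a Gaussian random field
  (exponential variogram, circulant embedding) and nugget, and a clustered
  inventory design (4-plot square templates, 150 m spacing, ≥ 4 km between
  clusters).

Rasters are carried as plain-text ESRI ASCII grids (`.asc`) with a `.crs`
sidecar naming the projected CRS; plot tables are CSV
(`plot_id, cluster_id, x, y, soc_t_ha`).

## Worked example

```python
import numpy as np
from socmap import (make_landscape, extract_at_plots, QRFParams, QRForest,
                    make_spatial_folds, cross_validate, predict_map,
                    sensitivity_map, percent_error_map, national_total,
                    UncertaintyMaps)

land = make_landscape(n_rows=288, n_cols=288, cell_size_m=90.0,
                      n_clusters=28, min_cluster_sep_m=4000.0, seed=42)
plots, stack, mask = land.plots, land.stack, land.forest_mask
design = extract_at_plots(stack, plots)[stack.names]
cats = stack.categorical_names()
params = QRFParams(n_trees=200, seed=42)

folds = make_spatial_folds(plots, k=10, seed=42)
cv = cross_validate(plots, design, folds, [params], categorical=cats)
print(f"spatial 10-fold CV: RMSE = {cv.rmse:.2f} t C/ha, R2 = {cv.r2:.2f}")

forest = QRForest(params, categorical=cats).fit(design, plots["soc_t_ha"].to_numpy())
mean, model_sd = predict_map(forest, stack, mask)
sens = sensitivity_map(plots, design, stack, folds, params, mask, categorical=cats)
perc = percent_error_map(mean, model_sd, sens)
est = national_total(UncertaintyMaps(mean, model_sd, sens, perc))
print(f"mean SOC density: {np.mean(mean.valid_values()):.1f} t C/ha")
print(f"total stock: {est.total_mt:.3f} Mt C over {est.cell_count} cells "
      f"({est.cell_area_ha} ha each), SE = {est.se_percent:.2f}% ({est.se_mode})")
```

prints

```
spatial 10-fold CV: RMSE = 18.83 t C/ha, R2 = 0.09
mean SOC density: 79.9 t C/ha
total stock: 5.082 Mt C over 78538 cells (0.81 ha each), SE = 0.09% (independence)
```

The 112 plots in 28 clusters see a landscape whose plot-scale noise
(SD ≈ 18 t C ha⁻¹) is about twice the covariate-predictable spread
(SD ≈ 10 t C ha⁻¹), so the honest leave-location-out R² is low while the
mean map and density remain well estimated — the situation typical of SOC
mapping in highly heterogeneous mountain terrain. The independence-mode SE
shrinks with the cell count; the fully correlated mode (`se_mode=
"correlated"`) gives the conservative upper bound.

The same pipeline is exposed as a CLI (`socmap synth | covariates | fit |
cv | predict | uncertainty | aoa | variogram | compare | total`), driven by
a small YAML config naming the layer paths and model settings (see
`socmap.config`).

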