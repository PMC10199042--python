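# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## The prediction model

SOC density at a cell is modelled as an unknown function of scorpan
covariates — soil class (s), climate proxies (c), organism/disturbance
proxies (o), relief (r), parent material (p), and implicit spatial position
through the covariates themselves; no temporal dimension is modelled (all
covariates are static).

The estimator is a quantile regression forest: a bagged ensemble of CART
trees (variance-reduction splits, `mtry` features sampled per split,
minimum leaf size `min_node_size`) in which each leaf stores the bootstrap
multiplicities of its in-bag observations. The conditional distribution at
a point x is the Meinshausen mixture: each tree contributes weight
`multiplicity / (leaf total · n_trees)` to the training responses sharing
x's leaf. Mean and SD are exact moments of that weight vector; quantiles
use the inclusive weighted empirical definition — the smallest response
whose cumulative weight reaches q, with no interpolation — one convention
used everywhere in the package (QRF quantiles, DI thresholds).

Defaults: `n_trees = 500`, `mtry = ⌈p/3⌉`, `min_node_size = 5`, all
seedable and exposed in the config. Tree induction is delegated to
scikit-learn's `DecisionTreeRegressor`; bootstrap bookkeeping, leaf-weight
aggregation, OOB error, permutation importance (mean decrease accuracy:
increase in OOB RMSE after permuting a covariate, averaged over seeded
permutations) and partial dependence are implemented here.

**Categorical covariates.** Levels are target-mean encoded *per tree from
that tree's bootstrap sample only*. For a single variance-reduction split,
ordering levels by mean response is equivalent to exhaustive subset search
(Fisher's optimal-partition result), so this encoding preserves the split
quality of a native categorical CART while letting the numeric tree code do
the work. Computing the encoding per tree in-bag is essential: a global
target encoding leaks the response into out-of-bag rows — with many small
classes the encoded column becomes a noisy copy of y — which silently
corrupts OOB error and inflates the importance of high-cardinality
categorical covariates. A level unseen by a tree's bootstrap sample is
routed to that tree's in-bag mean response.

## Spatial cross-validation and uncertainty

Plots arrive in clusters (~150 m apart within a cluster, kilometres
between clusters). Random k-fold CV splits clusters across folds, so noise
shared within a cluster leaks into the test set and the error estimate is
optimistic. Leave-location-out CV deals whole clusters to folds (shuffled,
then greedily to the smallest fold, balancing plot counts). The package
treats the spatial estimate as the honest one; the random/spatial contrast
is itself a diagnostic and is asserted as an ordering (spatial RMSE ≥
random RMSE in ≥ 8/10 seeded replicates when the noise range far exceeds
the within-cluster spacing).

Three error surfaces accompany the mean map:

- *model SD*: per-cell SD of the QRF conditional distribution;
- *sensitivity SD*: per-cell sample SD (ddof = 1) across the k = 10 mean
  maps refitted on each spatial fold's training set — the uncertainty
  attributable to which clusters happened to be sampled;
- *percent error* = 100 · (model SD + sensitivity SD) / mean. Cells with
  mean ≤ 1 t C ha⁻¹ (configurable floor) are set to nodata rather than
  letting the ratio blow up; their count is logged.

**Stock totals.** Total = Σ mean × cell area, in Mt C. How per-cell SEs
aggregate depends on the spatial correlation of errors, which the per-cell
surfaces do not determine; the package therefore reports both limiting
modes — independence (root sum of squares, SE shrinks like 1/√n and is
surely too small for spatially correlated model error) and full correlation
(plain sum, surely too large) — with independence as the default label,
and makes no claim about where in between the truth lies. All map
reductions use `math.fsum` over a fixed row-major traversal, so totals
recomputed from written rasters agree bit for bit.

## Area of applicability

DI of a query = minimum Euclidean distance to a training plot in the space
of continuous covariates standardized by training mean/SD and multiplied
by permutation-importance weights (floored at 0, normalized to mean 1 —
the weighting is scale-free), normalized by the mean pairwise training
distance. Categorical covariates are excluded from the distance by default
(standardization over unordered codes is undefined). The cutoff is the
inclusive 0.95 quantile of cross-validated training DIs, each plot scored
against the training plots outside its own (cluster-based) fold. AOA = 1
where DI ≤ cutoff.

Because the weights come from the fitted forest, the screen can only
detect extrapolation along directions the model itself found informative:
if a truncated training range makes a covariate locally uninformative, its
importance — and hence its DI weight — collapses, and extrapolation along
that axis goes unflagged. The high-elevation detection test therefore uses
an elevation-dominant generative model, matching the study system where
elevation is the leading covariate.

## Residual variograms

Empirical semivariance `γ(h) = Σ (zᵢ−zⱼ)² / (2 N_bin)` over regular
half-open distance bins on (0, 25 km], 50 bins by default; pairs exactly on
a bin edge fall in the lower bin. The envelope is the pointwise (not
simultaneous) min/max over 99 seeded permutations of residuals over
locations. No variogram model is fitted in the pipeline; the diagnostic is
whether the observed curve leaves the envelope, particularly at short lags.

## Terrain operators

- Slope: Horn 3×3 stencil, degrees; edge cells use replicated padding.
- TPI: elevation minus the mean of a square window (default 100 m, ≥ 3×3
  cells, centre excluded).
- TWI: `ln(a / tan β)` with specific contributing area `a` from D8
  steepest-descent routing after priority-flood sink filling (epsilon
  gradient 1e-4 m so filled flats drain), and `tan β` from the Horn
  stencil floored at 1e-3. D8 after priority flood was chosen over
  multi-direction routing because every step has an exhaustive small-grid
  oracle.
- Wind exposure: a documented horizon-based surrogate for GIS wind-effect
  indices — per direction, the maximum signed angle to terrain within a
  search radius (default 300 m, 8 directions); directional index
  `1 − (2/π)·angle`, averaged and clipped to [0.5, 1.5]. Exactly 1 on flat
  terrain, > 1 on summits, < 1 in pits.
- Edge distance: exact Euclidean distance transform; forest cells adjacent
  to non-forest get one cell size (0 is reserved for non-forest itself,
  which is nodata in the output).
- Cost surface: Dijkstra on the 8-connected grid with directed edge costs
  `dist · 0.72 s/m + max(Δz,0) · 6 s/m + max(−Δz,0) · 0 s/m`
  (Naismith-style defaults, configurable) from all road cells at once.

## The synthetic study area

The generator emulates the statistical structure the analysis assumes, not
any real geography:

- DEM: spectral synthesis with a power-law spectrum (exponent 3.2),
  rescaled to span the relief amplitude (default 3000 m) — smooth at cell
  scale with realistic large-scale ruggedness.
- Covariates: terrain derivatives computed by the real operators; NDVI as
  a productivity proxy declining quadratically with elevation plus a smooth
  random field; soil (21 classes) and parent material (11 classes) as
  equal-frequency elevation bands with large band noise (30–40% of the
  relief), so they track elevation zones only loosely rather than
  duplicating the elevation signal; a binary protected-area disc; forest =
  everything below the ~96th elevation percentile (a treeline) minus a
  border ring; roads along the southern edge with a spur.
- SOC truth: `intercept + Σ coef·layer + class offsets`, plus a Gaussian
  field with exponential variogram simulated by circulant embedding
  (practical-range convention: correlation exp(−3) at the stated range)
  plus an independent nugget. Negative draws are truncated at 0 and
  counted. Default noise: partial sill 225 (15 t/ha SD) with 2 km range —
  well above the 150 m within-cluster spacing, so cluster-mates share
  noise — and nugget 100 (10 t/ha SD). The default intercept (20) puts the
  mean density in the 60–80 t C ha⁻¹ band typical of Himalayan forest
  topsoils.
- Plot design: cluster anchors rejection-sampled on the forest mask at
  ≥ 4 km separation; 4 plots per cluster on a square 150 m template
  (plots-per-cluster is a fixture choice, configurable).

Under these defaults the covariate-predictable spread (SD ≈ 10 t/ha
within the forest mask) is about half the noise SD, so spatial-CV R² is
deliberately low (~0–0.1): the regime of weak covariate–SOC relationships
in heterogeneous mountain terrain. Tests that need a strongly identified
covariate (the AOA elevation screen) construct their own
elevation-dominant coefficient set and say so.

What passing tests do **not** show about real data: the generative model is
linear with additive stationary noise, so they demonstrate correctness and
calibration of the machinery, not that a QRF recovers real, nonlinear,
nonstationary SOC surfaces; NDVI is simulated, not derived from
reflectance; no disturbance history, measurement error model, or covariate
error is simulated.

## Problem sizes and numerical choices

Test and acceptance runs use scaled-down extents chosen by the package:
map products on a 288² grid of 90 m cells (26 km, 28 clusters), interval
calibration on 768² grids of 120 m cells (200 clusters, 800 plots, 10
replicates), CV-ordering replicates on 320² grids (20 clusters). The
within-cluster spacing (150 m), cluster separation (≥ 4 km), template
geometry and noise parameters are held at the study-design values
throughout; only extent, cell size and cluster count scale. Large grids
use analytic stand-ins for the two flow-routing covariates
(`with_terrain=False`) since priority-flood/Dijkstra on millions of cells
dominates runtime without adding information to those tests; each stand-in
carries an independent smooth component so the covariates stay
non-collinear.

Determinism: every stochastic step takes a seed (forests spawn per-tree
seeds from a `SeedSequence`; tie-breaks in cluster dealing, D8 routing and
fold assignment are fixed by ordering). Raster text I/O prints 17
significant digits, so write→read roundtrips are bit-exact. Geographic
(degree-unit) CRS are rejected at construction: all distance and area math
assumes metres.

## Known limitations

- The QRF categorical handling is the ordered-by-in-bag-mean encoding, not
  a native subset search at every node; with `mtry < p` the per-tree (not
  per-node) ordering is a mild approximation.
- Sensitivity maps inherit the spatial-fold randomness; a different fold
  seed gives a slightly different sensitivity surface (the k = 10
  convention is kept, other k warn).
- The AOA screen cannot flag extrapolation along covariates the fitted
  model ignores (see above).
- No reprojection or resampling: all inputs must share one grid; the map
  comparison aggregates only by integer block factors (30 m → ~250 m and
  ~1 km correspond to factors 8 and 33, approximations by construction).
- Totals assume a constant cell area (projected CRS in metres).
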