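# Methods

This note documents the models, assumptions and numerical choices behind
each stage of the pipeline. It is the place to look before changing a
default.

## Trial simulator (`fieldsim`)

**Layout.** Plots of `plot_dims` = 1.8 × 4 m hold three 0.6 m row strips
(16 plants at 0.25 m spacing); 160 plots fill four columns of 40 with 1 m
between columns and 0.5 m between consecutive plots. Coordinates are local
planar metres with the origin at the trial's south-west corner — projection
machinery adds nothing to the analysis, and the real-data readers accept any
planar CRS as long as all inputs share it. Row polygons are inset 1 cm per
side so adjacent rows are strictly disjoint (identical point-in-polygon
assignment regardless of boundary conventions).

**Canopy model.** Each plant is a radial parabolic bump
h·max(0, 1 − (d/r)²) with apex height drawn uniformly from the
season-scaled `canopy_height_range` and a fixed radius (default 0.12 m, just
under half the plant spacing, so bumps do not overlap). A sum of bumps has a
closed-form volume (π r² h / 2 each) and closed-form volume above any
horizontal datum (π r² (h − c)² / (2h)), which gives every volume test an
analytic oracle. The closed form for the above-datum volume is exact only
while bumps do not overlap; the summer seed-head spikes do overlap their
parent plant, so end-to-end volume checks use fine-grid quadrature of the
summed surface instead, which is exact for any configuration.

**Seasons.** The trial spans vegetative (winter, late spring) and
reproductive (summer) stages. Seasons scale the height/density ranges
(winter 0.6/0.85, late spring 1.0/1.0, summer 1.25/0.9 — chosen to mimic the
qualitative pattern of slow winter growth and tall, partly senescent summer
canopies), and in summer a `reproductive_fraction` (default 0.3) of plants
carries an extra tall narrow spike (height × 1.8, radius 3 cm) emulating
bolted seed heads. Winter harvests weigh whole plots only; the simulator
therefore withholds the row-level FM table for winter, which is what forces
winter out of the combined row-level dataset downstream.

**Fresh mass.** FM = ρ · volume · density + N(0, σ), truncated at zero, with
ρ = 3000 g per m³ per density unit and σ = 10 g by default. ρ was chosen so
that default canopies weigh on the order of 10²–10³ g per row, the range of
real row harvests; σ of 10 g is a plausible scale-plus-handling error. The
per-row density (uniform in `canopy_density_range`) stands in for the
unobservable tiller/leaf/water density that makes volume alone an imperfect
biomass predictor — exactly the gap the LV_Den and NDVI covariates are meant
to fill.

**LiDAR survey.** One straight pass per row along its centreline at 1.2 m/s;
the 55–123° fan (1° steps, 500 Hz, sensor 1.127 m above ground) reaches
±0.8 m laterally, so each pass also sees the neighbouring row. Per frame the
canopy profile along the scan plane is sampled at 2 mm and each beam marches
to its first surface crossing (canopy or ground), plus Gaussian range noise
(default 3 mm). Frames are ceil(duration × 500) per pass, fixes
ceil(duration × 5); because the fix clock is 100× slower, the last frames of
a pass always trail the last fix — see the fusion tolerance below. Not
modelled (out of scope): multiple returns, beam divergence, wind motion,
within-canopy penetration.

**Multispectral.** The scene is a per-pixel linear soil/vegetation mixture:
where the summed canopy surface is above zero the vegetation endmember
(NIR 0.55, RED 0.05, …) is weighted by the row's density, elsewhere bare
soil (NIR 0.20, RED 0.18, NDVI ≈ 0.05). DN = gain × reflectance + offset +
noise per band; the five-panel tarp (3/6/11/22/33 %) is painted flat in
every band just south of the trial. Ground sample distance defaults to
2.08 cm. No BRDF, vignetting or shadowing — the point is to exercise the
calibration and zonal-statistics code, not radiative transfer.

**Sonar.** Two downward sensors per row at ±0.10 m from the centreline,
10 Hz each, 1.4 m/s, Gaussian noise 5 mm; distance = mount height − surface
height (ground on bare soil). One sample per 14 cm of travel per sensor.

**What the simulator does not emulate.** Real canopies are continuous along
the row, partially occlude themselves, move in wind, and have within-canopy
returns; real NDVI saturates and varies with sun angle; real FM error is not
Gaussian. Passing tests therefore demonstrate that the *extraction and
modelling machinery* is correct and convergent, not that the specific R²
values would be attained in a field.

## LiDAR metrics (`lidar_metrics`)

**Fusion.** Frames and fixes merge on timestamps: sensor position is linear
interpolation between bracketing fixes; heading comes from the fix field or
finite differences. A beam of elevation θ (90° = nadir) and range r maps to
z = sensor_height − r·sin θ and a signed lateral offset r·cos θ
perpendicular to the heading. The track is split into contiguous segments
wherever the fix spacing exceeds two GPS intervals (idle gaps between
passes); interpolation never crosses a gap, and each segment extrapolates
linearly up to one GPS interval past its ends — exactly the overhang a
500 Hz scanner has over a 5 Hz receiver. Frames further out raise an error.
No-return and non-finite ranges are dropped before clipping.

**Metrics.** Points are clipped to the polygon by point-in-polygon test.
LV_Den = (# points with z > cutoff) / (# points), cutoff 0.05 m matching the
5 cm harvest cut so that predicted mass corresponds to harvestable mass.
LV_PH = mean z of above-cutoff points (missing when none). LV sums
cell_area × max(0, cell_height − cutoff) over an axis-aligned grid (default
2 cm) anchored at the polygon's lower-left corner; empty cells contribute
zero — no infill, so the scanner never gets credit for canopy it did not
see.

**Per-cell summary.** The default cell height is the **mean** of the cell's
returns. For a first-return cloud the cell mean converges to the surface
integral (measured −1 % at 2 cm cells on analytic canopies, < 0.5 % change
on halving the cell). The per-cell **maximum** (available as
`cell_stat="max"`) is preferable for real clouds where ground hits leak
through sparse canopy, but on steep canopies it is biased high by roughly
slope × cell size (+20–26 % measured on the simulated bumps), so it is not
the default. Two consequences worth knowing: with the mean summary, adding
points to a cell can lower its estimate (monotonicity under added points
holds only for max), and with either summary the estimate is exact for
slab-like canopies whose edges align with the grid, and off by at most one
boundary-cell ring otherwise.

**Ground plane.** z = 0 by construction in simulation. For real data a
per-survey ground offset (e.g. a low percentile of z) can be subtracted as a
pre-step; it is off by default because no universal choice is safe.

## Spectral metrics (`spectral_metrics`)

Empirical-line calibration regresses nominal panel reflectance on mean panel
DN (OLS, per band independently), then applies reflectance = slope · DN +
intercept pixel-wise, clipping to [0, 1]. At least two panels with distinct
reflectances must intersect the raster; a flat panel response is a singular
fit and an error. NDVI is computed per pixel on the calibrated rasters and
then averaged per polygon — mean-of-NDVI, not NDVI-of-band-means; the two
differ on heterogeneous pixels and the per-pixel form is the one that
matches "NDVI image then zonal extraction". Pixels with NIR + RED = 0 are
masked. Zonal statistics use pixel-centre containment with no partial-pixel
weighting: at ~2 cm pixels against 0.6 m rows the boundary error is
negligible and the rule is deterministic.

## Sonar metrics (`sonar_metrics`)

Height = mount height − distance, clipped at zero; Sonar_PH is the mean over
all in-polygon samples, pooling the row's two sensors (a median is available
via `stat="median"` for spiky traces). Mount height is a required input —
it is rig-specific and must come from the platform configuration. Distances
exceeding the mount height by more than 5 cm are logged and clipped.

## Phenotype tables (`phenotable`)

Assembly inner-joins the metric tables and the FM table on `row_id`
(duplicate keys are an error, not a silent overwrite); rows missing any
phenotype are dropped and counted in the log. Plot aggregation: FM and LV
sum; LV_PH and Sonar_PH average; NDVI is the area-weighted mean of row
values (equal-area rows make this a plain mean); LV_Den is recomputed as the
pooled ratio Σ above-cutoff / Σ total points when counts are available —
this keeps the "ratio of points" definition exact at plot level — else the
mean of row ratios. Season combination applies the trial's filters (winter
plot-only; late spring minus the 80 faulty-mower plots; summer complete) and
keeps `season` as a column. The filters are applied as stated, and the
resulting counts (720 row-level, 400 plot-level for a full trial) follow
from them; no target count is imposed.

## Models (`models`)

OLS via `numpy.linalg.lstsq` on explicitly built design matrices (intercept
always included; interaction columns are element-wise products). Rank
deficiency is detected up front and reported with the names of removable
terms. Conventions, spelled out because they differ across software:

- Adjusted R² = 1 − (1 − R²)(n − 1)/(n − p); RSE = √(SSE/(n − p));
  RMSE = √(SSE/n); PER = RSE / mean(response) — a relative prediction error,
  defined by this package.
- AIC = n ln 2π + n ln(SSE/n) + n + 2(p + 1) and BIC with ln(n)(p + 1): the
  full Gaussian log-likelihood including the 2π constant, counting the error
  variance as a parameter (R's `AIC()` convention; statsmodels omits the
  variance parameter, hence its values are smaller by exactly 2 and ln n).
- Mallows Cp = SSE/s²_full − n + 2p with s²_full from the all-predictors
  main-effects model, so the full model's Cp equals its own p identically —
  a built-in self-check.

Best-subset search is exhaustive (31 subsets for five predictors; no
branch-and-bound needed at this size), flags the minimum-SSE subset per
size, and ranks globally by Adjusted R² (higher), Cp and BIC (lower); ties
break toward fewer predictors, then lexicographic order. Correlation uses
Pearson r with a two-sided t-test and stars at p ≤ 0.001/0.01/0.05.

## Cross-validation (`validation`)

Three schemes: repeated k-fold (default k = 10, 10 repeats — "repeated
ten times" read as 10 repeats of 10-fold; both are flags), leave-one-out
(deterministic), and random split (default 80/20, 100 repeats). Folds are
plain random permutations (no stratification variable exists) drawn via
scikit-learn splitters seeded from a `SeedSequence` per replicate, so the
whole assignment is reproducible from one scheme seed. Metrics use held-out
predictions only; per replicate, R² is the pooled out-of-fold 1 − SSE/SST
(the per-fold-averaged R² is also reported, since the two definitions differ
and both appear in practice); aggregates are means over replicates. A
training fold smaller than the parameter count is an error suggesting a
smaller k. LOOCV has a never-refitting oracle: the PRESS/hat-matrix identity
e_i/(1 − h_ii), which the tests require to match to 1e-8.

## Pipeline and problem sizes

`run-all` executes the stages for the configured seasons and writes every
intermediate table plus a manifest (config snapshot, seeds, per-stage record
counts, timings). Two extraction paths exist: `sensors: full` renders raw
streams and runs the real extractors; `sensors: fast` computes the same five
phenotypes analytically from the canopy truth (exact volumes, cover
fractions, mixture NDVI) — the fast path is for dataset-scale statistical
studies, the full path is what validates the extractors. Dataset-level tests
and the reproduction script use the fast path at the full 160-plot trial and
the full sensor path on 2–4-plot surveys at a 150 Hz scan rate (along-track
spacing still < 1 cm), which keeps the whole suite under a minute of
simulation while the geometry is resolution-checked separately.

## Known limitations

- First-return LiDAR only; no occlusion correction, so dense leaning
  canopies would bias LV low in ways the simulator does not reproduce.
- The empirical-line model is per-band affine; sensor non-linearity or
  vignetting would need a richer calibration.
- The plot-level combined dataset follows the stated filters exactly;
  datasets curated with additional unrecorded exclusions will differ in
  count, and no attempt is made to guess those exclusions.
- Season effects are scalar multipliers plus a spike component — adequate
  for exercising combined-season logic, not a phenological model.
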