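# phenomass

Sensor-based prediction of forage biomass in row-plot field trials.

Breeding perennial ryegrass for yield requires fresh-mass (FM) measurements
on hundreds of plots, several times per growing season. Destructive harvest
is accurate but slow and expensive; ground- and air-based sensors offer a
non-destructive alternative if their digital readouts can be turned into a
biomass prediction that holds up *across* seasons, not just within one.
`phenomass` implements that analysis end to end for trials laid out as plots
of three single-cultivar rows:

1. **Simulate** a trial (160 plots × 3 rows by default) with ground-truth
   canopies and the raw streams the sensors would record: 2D line-scan LiDAR
   frames plus an RTK GPS track, five-band multispectral rasters with a
   calibration tarp, ultrasonic sonar distance traces, and per-row harvest
   weights generated from the mass law FM = ρ · volume · density + ε.
2. **Extract** five digital phenotypes per row/plot polygon:
   - `LV` — LiDAR canopy volume (m³), grid surface integration above the
     5 cm cutting datum,
   - `LV_Den` — fraction of LiDAR returns higher than 5 cm,
   - `LV_PH` — mean LiDAR height of above-datum returns (m),
   - `Sonar_PH` — mean ultrasonic canopy height (m),
   - `NDVI` — (NIR − RED)/(NIR + RED) on tarp-calibrated reflectance,
     averaged per polygon.
3. **Model** FM with multiple linear regression. The named family uses
   R-style crossing (A × B = A + B + A:B):

   | model | formula |
   |-------|---------|
   | M1 | FM ~ NDVI × Sonar_PH |
   | M2 | FM ~ NDVI × LV_PH |
   | M3 | FM ~ LV × NDVI |
   | M4 | FM ~ LV × LV_Den |
   | M5 | FM ~ LV × (LV_Den + NDVI) |
   | M6 | FM ~ LV × LV_Den × NDVI |

   M3–M6 follow the mass premise: volume times a density proxy. A best-subset
   search additionally fits all 31 main-effects subsets of the five
   phenotypes and ranks them by Adjusted R², Mallows Cp and BIC.
4. **Validate** the chosen model (typically M4, which needs only the LiDAR)
   with repeated k-fold, leave-one-out and random-split cross-validation,
   reporting out-of-fold RMSE, R² and MAE.

Seasonal datasets are combined with the trial's filters: winter FM exists
only at plot level, and late spring loses the plots whose harvest was
spoiled by a faulty mower, so the combined row-level set holds
240 + 480 = 720 records.

## Worked example

```python
from phenomass import fieldsim as fs
from phenomass.models import expand_model, fit_ols, model_metrics
from phenomass.validation import CVScheme, cross_validate

df = fs.simulate_phenotype_table(n_rows=480, seed=1, target_r2=0.9)
for name in ("M1", "M3", "M4", "M6"):
    m = model_metrics(fit_ols(expand_model(name), df))
    print(f"{name}: R2={m.r_squared:.3f} RSE={m.rse:.1f} g")

cv = cross_validate(expand_model("M4"), df,
                    CVScheme(kind="repeated_kfold", k=10, repeats=10, seed=1))
print(f"M4 10x10-fold CV: R2={cv.r_squared:.3f} RMSE={cv.rmse:.1f} g")
```

prints

```
M1: R2=0.825 RSE=84.1 g
M3: R2=0.837 RSE=81.2 g
M4: R2=0.897 RSE=64.5 g
M6: R2=0.899 RSE=64.2 g
M4 10x10-fold CV: R2=0.895 RMSE=64.8 g
```

The dataset is drawn from the generative mass law with measurement noise set
so the volume–density signal explains 90 % of FM variance. The
volume-only-proxy models (M1, M3) trail the volume × density model (M4),
whose interaction term is exactly the generating signal; adding NDVI (M6)
buys almost nothing; and the out-of-fold R² sits within 0.002 of the
in-sample value at n = 480, i.e. the model generalizes.

The full pipeline — simulate, extract from rendered sensor streams, assemble,
fit, cross-validate — runs from one config file:

```bash
phenomass run-all --config demo.yaml     # demo.yaml needs at least "seed: <int>"
```

Each stage is also a standalone subcommand (`simulate`, `lidar-metrics`,
`ndvi-extract`, `sonar-height`, `assemble`, `fit-models`, `validate`)
operating on the previous stage's GeoJSON/CSV/TIFF files.

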