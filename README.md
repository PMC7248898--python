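# gflai

Physically based retrieval of **leaf area index (LAI)** — half the total
green leaf area per unit ground area, m²/m² — from four-band
(blue/green/red/near-infrared) surface reflectance, for mixed
("multi-species") vegetation where no single empirical regression fits all
plant types.

The package is aimed at remote-sensing scientists working with broadband
16 m-class imagery (blue 450–520, green 520–590, red 630–690, NIR
770–890 nm) who want to compare retrieval strategies rather than commit to
one: it implements the full study design of simulating a canopy
reflectance database with a radiative transfer model, inverting it two
ways, and scoring every sensible feature choice.

## What it does

* **Forward simulation** — truncated-Gaussian sampling of ten
  leaf/canopy/soil parameters (LAI 0–7 m²/m², chlorophyll 0–90 µg·cm⁻²,
  leaf inclination 30–80°, …), a pluggable canopy reflectance model
  (PROSAIL5B if installed, or a built-in analytic two-stream toy model
  `R = R_soil e^(−k·LAI) + R_∞ (1 − e^(−k·LAI))`), boxcar resampling to
  the four sensor bands, additive Gaussian reflectance noise.
* **Look-up-table inversion** — a 100,000-entry database searched with the
  relative-RMSE cost
  `RRMSE = sqrt((1/m) Σ ((R_obs − R_sim)/R_obs)²)`
  and solved by averaging the LAI of the best 10% of entries
  (multi-solution averaging against ill-posedness).
* **Hybrid Gaussian-process inversion** — an exact GP with a squared
  exponential kernel (one length-scale hyperparameter + white noise)
  trained on 3000 simulated (feature → LAI) pairs.
* **25 retrieval strategies per method** — all 15 non-empty combinations
  of the four bands plus 10 published vegetation indices (NDVI, DVI, TVI,
  EVI2, GNDVI, GRVI, MCARI-type, MNLI, MSAVI, MTVI2), each scored with
  R² = 1 − SS_res/SS_tot and RMSE against validation plots.
* **Mapping** — per-pixel inversion of a georeferenced four-band raster
  into an LAI map with validity masking, plus plot-to-pixel matching by
  coordinates.
* **Synthetic study inputs** — a generator for field-campaign plot tables
  (default 29 plots) and small georeferenced scenes with known true LAI,
  since real campaign data of this kind is rarely redistributable.

## Worked example

```python
import gflai as g

# a 29-plot synthetic campaign with known truth, σ = 0.01 band noise
plots = g.simulate_field_campaign(n_plots=29, noise_sigma=0.01, seed=7)

# MSAVI strategy, both engines
lut = g.build_lut(strategy="MSAVI", n_entries=10_000, seed=1, noise_sigma=0.01)
est_lut = [g.invert_lut(g.extract_features(r, lut.strategy).values, lut).lai_estimate
           for r in plots[["B1", "B2", "B3", "B4"]].to_numpy()]

train = g.make_training_set(strategy="MSAVI", n=3000, noise_sigma=0.01, seed=1)
model = g.train_gpr(train, seed=1)
from gflai.features import feature_matrix
est_gpr, sd = g.predict_gpr(model, feature_matrix(
    plots[["B1", "B2", "B3", "B4"]].to_numpy(), model.strategy))

for name, est in [("LUT", est_lut), ("GPR", est_gpr)]:
    r2, rmse = g.score(plots["true_lai"], est)
    print(f"MSAVI-{name}: R2 = {r2:.4f}, RMSE = {rmse:.4f} m2/m2")
```

prints

```
MSAVI-LUT: R2 = 0.6040, RMSE = 1.2442 m2/m2
MSAVI-GPR: R2 = 0.5974, RMSE = 1.2545 m2/m2
```

Both engines explain roughly 60% of the LAI variance across the
synthetic multi-species plots; the residual ~1 m²/m² RMSE is dominated by
between-plot variation in leaf chemistry and canopy structure (the
"multi-species" confound), not by sensor noise.  Under an identifiable
prior in which only LAI varies, the same machinery recovers LAI to better
than 0.001 m²/m² — see `docs/methods.md`.

The 50-row strategy comparison and the GPR learning curve come from one
call each:

```python
results = g.compare_strategies(plots, g.enumerate_strategies(),
                               lut_size=10_000, gpr_size=3000, seed=1)
sweep = g.training_size_sweep((500, 1000, 2000, 3000, 5000), replicates=3, seed=1)
```

A `gflai` command-line interface wraps the same functions
(`gflai simulate-campaign`, `build-lut`, `train`, `invert`, `map`,
`compare`, `sweep`; see `gflai --help`).

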