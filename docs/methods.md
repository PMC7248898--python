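# Methods

`gflai` estimates leaf area index (LAI, half the total green leaf area per
unit ground area, m²/m²) from four broad spectral bands — blue (450–520 nm),
green (520–590 nm), red (630–690 nm) and near-infrared (770–890 nm), the
band set of a wide-field 16 m multispectral camera — by inverting a canopy
radiative transfer model.  This note documents the models, the numerical
choices, and what the synthetic experiments do and do not demonstrate.

## Forward model

The retrieval is *physically based*: a forward model maps a vector of
leaf/canopy/soil parameters and a sun/sensor geometry to top-of-canopy
reflectance.  Two backends share one interface:

* **PROSAIL5B** (PROSPECT-5 leaf optics coupled to the 4SAIL canopy
  bidirectional reflectance model), available when the optional `prosail`
  package is installed.  Its physics are delegated entirely to that
  library; this package never re-derives them.
* **Toy two-stream canopy** (built in, default): exponential mixing of a
  soil background and an infinite-canopy spectrum,

      R(λ) = R_soil(λ) e^(−k·LAI) + R_∞(λ) (1 − e^(−k·LAI)),

  with extinction k = cos(ALIA).  The endmembers respond to the other
  parameters — visible R_∞ decays with chlorophyll content, the NIR plateau
  grows with leaf structure N and shrinks with brown pigment and water, and
  the soil line scales with the brightness factor psoil — so that non-LAI
  variability confounds the signal qualitatively the way leaf chemistry
  does in real mixed canopies.  The model is closed-form, strictly monotone
  in LAI wherever the endmembers differ, and hence exactly invertible:
  every parameter-recovery test in the suite uses it as ground truth.
  The hot-spot parameter and the view geometry are accepted but ignored by
  the toy model (it is hemispherically averaged by construction).

Hyperspectral output (400–1000 nm at 1 nm for the toy model, 400–2500 nm
for PROSAIL) is reduced to the four bands by an unweighted mean over each
band interval (boxcar response).  True instrument response curves are
rarely published at band-edge precision; a per-band weight table can be
supplied to override the boxcar.  Batch simulation exploits the toy
model's linearity in three fixed wavelength shapes and agrees with the
spectrum-then-resample path to ≤1e-12.

## Sampling the parameter space

Databases (LUT entries, training sets) draw every leaf/canopy/soil
parameter independently from a truncated Gaussian over its physical range
(LAI: 0–7 m²/m², mean 3.5, std 2.5; chlorophyll: 0–90 µg·cm⁻², mean 50,
std 40; leaf structure N: 1–2.5; average leaf inclination: 30–80°; etc.),
implemented with the inverse-CDF truncated-normal sampler so no draw ever
leaves its interval.  A distribution with `std = 0` or `law = "fixed"`
degenerates to its mean.  Sun/sensor geometry is one fixed triple per
database build, default (tts, tto, psi) = (30°, 0°, 0°); the actual
acquisition geometry of any given scene is a configuration input, not a
claim.

Two stock priors matter:

* `default_distribution_spec()` — the **multi-species study condition**:
  everything varies.  Under the toy model four bands then do *not*
  identify LAI (e.g. leaf inclination and LAI enter only through
  cos(ALIA)·LAI), so retrieval accuracy is capped by structural ambiguity
  exactly as mixed vegetation caps it in the field.
* `lai_only_spec()` — the **identifiability condition**: only LAI varies,
  everything else fixed at its mean.  The feature → LAI map is then a
  deterministic monotone function and noise-free inversion must recover
  LAI essentially exactly.  Recovery/consistency tests use this prior;
  study-level comparisons use the full one.

Reflectance noise is additive i.i.d. Gaussian per band (default
σ = 0.01 absolute reflectance, a typical post-atmospheric-correction
uncertainty for broadband sensors), clipped to [0, 1].  Noise is applied
to LUT entries, training features and synthetic observations alike, each
from its own seeded stream.

## Look-up-table inversion

The LUT holds n paired (feature, parameter) rows, default n = 100,000 —
the size long established as balancing accuracy against compute for this
family of retrievals.  The cost between an observation and a candidate is
the relative RMSE: for an m-band feature vector
`sqrt((1/m) Σ ((R_obs − R_sim)/R_obs)²)`, and for a single vegetation
index the absolute relative error.  Costs are sorted ascending (stable,
ties by entry index) and the LAI values of the best `ceil(q·n)` entries
are averaged, q = 0.10 by default — multi-solution averaging that
regularises the ill-posed inversion.  `ceil` was chosen so a nonzero q
never yields an empty retained set.  Observed components with magnitude
below 1e-6 make a relative error undefined: band components are excluded
(m reduced); a fully undefined observation returns an invalid-flagged
solution so rasters can mask it.  Only the LAI column is reported; the
averaged full parameter vector is kept in the solution's provenance.

## Gaussian-process inversion

The hybrid route trains a GP regressor on forward-simulated
(features → LAI) pairs, default 3000 — the size where the learning curve
plateaus (see the sweep harness).  The covariance is an isotropic squared
exponential with one shared length-scale — a single kernel hyperparameter
— times a signal-variance constant, plus a white-noise term.  Features are
standardised to training mean/std before kernel evaluation; constants are
stored with the model.  Hyperparameters maximise the log marginal
likelihood (L-BFGS with one restart).

Exact-GP likelihood optimisation is O(n³) *per optimiser step*, which is
prohibitive at n = 3000 inside a 50-strategy comparison, so the search
runs on a seeded subsample of at most 800 training points and the final
model is then conditioned on the **full** training set with the optimised
hyperparameters held fixed (one Cholesky).  With thousands of points in a
1–4-dimensional feature space the subsample estimates the length-scale as
well as the full set does; the package's recovery tests (hold-out RMSE
≈ 5e-5 m²/m² noise free) bound the cost of this shortcut.  A 1e-8 jitter
and a 1e-8 white-noise floor keep the Cholesky positive definite on
noise-free data.

Posterior means are clipped to the physical support [0, 7] m²/m² (the raw
value is available via `return_raw=True`); the posterior std is reported
untouched.  Rows with non-finite features (masked index values) predict
NaN rather than raising.

## Evaluation

Accuracy is scored with R² = 1 − SS_res/SS_tot (which can be negative; it
is *not* a squared correlation) and RMSE in m²/m².  Non-finite pairs are
dropped pairwise and the surviving n reported.  The comparison harness
runs all 15 band subsets and 10 vegetation indices per method; strategies
of one method share one simulated database seed, so differences between
strategies are paired, not confounded with sampling noise.  Failures are
recorded per row and do not stop the run.  The learning-curve harness
reports mean ± std RMSE over replicates per training size because a single
stochastic realisation is seed-dependent.

## Vegetation indices

The ten indices are NDVI, DVI, TVI, EVI2, GNDVI, GRVI, MCARI-type, MNLI,
MSAVI and MTVI2, all computable from the four bands.  MSAVI uses the
canonical Qi formulation `[(2B4+1) − sqrt((2B4+1)² − 8(B4−B3))]/2`; the
MCARI-type and MTVI2 rows use the Haboudane triangular forms with
`sqrt(B3)` inside the discriminant.  Secondary typography in circulation
sometimes drops the radicals; a `variant="literal"` switch evaluates the
no-radical reading for comparison.  For reflectance in (0, 1] every
discriminant in the canonical forms is provably positive; for pathological
inputs (or zero denominators such as B4+B3 = 0) the index evaluates to NaN
and the pixel is masked downstream.

## Synthetic data

The campaign generator emulates a ~30-plot field validation set: per plot
a full parameter draw (so species-like heterogeneity is present), forward
modelling, band noise, plus cosmetic coordinates inside an arid-basin
bounding box and species labels drawn from a mixed desert-riparian flora
list.  The scene generator builds a small georeferenced raster (default
64×64, 16 m pixels) over a hidden LAI surface — linear gradient, random
blocky patches, or smoothed Gaussian noise — scaled into a configurable
range (default 0–4 m²/m², sparse arid vegetation), with a nodata border
strip to exercise masking.

What passing tests on these data demonstrate: the inversion machinery is
exact (LUT), consistent (mapping = per-pixel inversion), statistically
sound (GP recovers an identifiable signal to ≈0.05 % of the LAI range),
and well-behaved under noise and heterogeneity.  What they do not
demonstrate: accuracy on real imagery — the generator has no atmospheric
residuals, no adjacency or mixed-pixel effects, no spatially correlated
leaf chemistry, and its noise is white, so real-data errors will be
larger and differently structured.

## Mapping

Scenes are read/written as plain multiband float32 TIFFs with a JSON
sidecar holding the GDAL-style geotransform, CRS and nodata value
(default −9999).  Integer-scaled reflectance is supported via a scale
factor; values outside [0, 1] after scaling are masked.  Scene inversion
deliberately loops pixels through the scalar plot-level code path —
pixelwise consistency with scalar inversion is an invariant, not an
optimisation target — and records the strategy, engine and an input
checksum in the map's provenance.  Plots are matched to pixels by nearest
pixel center; plots outside the footprint are dropped with a warning and
counted, and several plots may share a pixel.

## Problem sizes in the shipped experiments

The packaged experiments use a 10,000-entry LUT and n = 3000 GP training
sets for the 50-strategy comparison, a 100-LUT randomized exactness check,
a 1000-entry self-inversion check, training sizes 500–5000 × 3 replicates
for the learning curve, and a 64×64 scene for mapping — sizes chosen so
the whole study re-runs from scratch in minutes on a single core while
keeping every statistical conclusion stable across seeds.  The LUT default
of 100,000 entries remains the production setting for real retrievals.

## Known limitations

* The toy model's structural ambiguity (cos(ALIA)·LAI) is a caricature of
  real canopy ambiguity; PROSAIL exhibits richer but related compensations.
* One fixed geometry per database: no per-pixel view-angle variation.
* Exact GP only; n ≫ 10⁴ training sets would need inducing-point
  approximations that are out of scope.
* The serialized model/LUT formats are internal (`.npz` + JSON) and not
  interchange formats.
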