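# Methods

This note records the models, conventions and numerical choices behind
`canopyhydra`, in the order the pipeline runs them.

## 1. Synthetic trial and scene model

### Design

`TreatmentDesign` encodes a split-plot trial: mulch levels {SM (straw),
FM (ridge film), NM (none)} crossed with supplementary irrigation
{W1, W2, W3}, each combination replicated (default 3) and repeated over
seasons (default 2): 27 plots per season, 54 plot-season samples.  The
treatment-to-plot layout is randomized once per seed and reused across
seasons, as in a real trial.

### Moisture

Leaf moisture content (LMC) is the water fraction of leaf fresh mass in
percent, `LMC = 100 (m_fresh − m_dry)/m_fresh` (`metrics.leaf_moisture_pct`).
The generator draws

    moisture = 70 + mulch effect + irrigation effect + N(0, 2)   [%]

with default effects SM +1.5, FM +2.5, NM 0 and W1 0, W2 +1.5, W3 +3.0,
clamped just inside (0, 100).  A baseline of ~70% with a spread of a few
percentage points is typical for well-watered legume canopies at
flowering, and puts the error metrics on the familiar percentage-point
scale (RMSE ≈ 1–2) a field study of this kind reports.

### Reflectance and texture

Each plot-season is a rectangular patch (default 24 × 24 px, leaving
18 × 18 valid 7×7-window centers) in a six-band raster.  Band b of plot k:

    mean_b(k)  = intercept_b + slope_b · moisture_k + N(0, plot_noise_sd)
    pixel(r,c) = mean_b(k) + texture field + N(0, noise_sd)

* Intercepts/slopes default to a typical green-canopy spectrum at 70%
  moisture (NIR ≈ 0.45, visible ≈ 0.04–0.08) with positive red-edge/NIR
  slopes and slightly negative visible slopes — wetter plots are brighter
  in the NIR and marginally darker in the visible.  Values fully outside
  [0, 1] are a configuration error; otherwise clamped.
* `plot_noise_sd` (default 0.003) is per-plot, per-band mean-reflectance
  noise: canopy density/background variation unrelated to leaf moisture.
  It does not average away over pixels and is what makes the retrieval
  realistically *partial*.  The default is calibrated once so that the
  headline validation RMSE of the model grid lands at ~1–1.7 percentage
  points, commensurate with the scale the moisture model targets.
  Without it the moisture → band-mean map would be invertible and every
  model would trivially reach R² ≈ 1.
* The texture field is white Gaussian noise smoothed with a Gaussian
  kernel (σ = 1 px), mean-centered within the plot (so it cannot move
  the plot mean), and scaled to variance `texture_link · moisture/100`
  (default `texture_link` = 0.002): wetter plots carry visibly more
  spatial variability, which is the planted signal the GLCM stage
  recovers.  This is deliberately the simplest texture-bearing model;
  it does not emulate rows, leaf shapes, specular glint or shadows.
* `noise_sd` (default 0.005) is white per-pixel sensor noise.

Scenes serialize as float32 multiband TIFF + GeoJSON plot polygons (raster
coordinates) + a moisture CSV; a read round-trip reproduces values to
float32 precision.  Identical config + seed gives bit-identical scenes.

What passing tests on this generator do **not** show: robustness to
georeferencing error, mixed soil/canopy pixels, atmospheric or
illumination drift, or real canopy texture — all out of scope here.

### Planted-pair tables

`planted_texture_table` makes a 48-column texture table with i.i.d.
features uniform on [0.5, 2.5] (positive, so all six index families are
defined) and moisture `70 + 3·z(index) + N(0, 0.8)` driven through one
designated pair and family.  It exercises the exhaustive search directly:
at these settings the planted pair must emerge as the family maximum in
≥95% of replicates.

## 2. Mean reflectance extraction

A pixel belongs to an ROI iff its center (col + 0.5, row + 0.5) is
strictly inside the polygon — half-open, so an axis-aligned integer
rectangle (c0,r0)–(c1,r1) covers exactly columns c0..c1−1 and rows
r0..r1−1.  This rule is load-bearing: edge-pixel counts differ between
conventions, so it is fixed, documented and tested rather than
configurable.  The plot reflectance is the arithmetic mean over unmasked
in-polygon pixels; an ROI left empty by masking raises, it never silently
returns zero.  Shadow/soil exclusion is available as an optional NIR-floor
threshold mask (off by default), standing in for the manual exclusion
practitioners do.

## 3. Vegetation indices

Ten indices are computed from the 6-band mean reflectance vector; names
and formulas are in `vegetation_indices.py`.  Conventions worth noting:

* **OSAVI** uses the *green* band by default, matching the workflow this
  package reproduces; `osavi_canonical=True` restores the standard
  red-band form.  The two differ materially.
* **MSAVI** defaults to the canonical closed form
  `0.5(2N+1 − sqrt((2N+1)² − 8(N−R)))`; a typographically ambiguous
  variant (leading `2N−1`, squared difference under the root) is kept
  behind `msavi_as_printed=True`.
* **RDVI** is read as `sqrt((N−R)/(N+R))`; a negative radicand raises.
* **MTCI/CI** take R_RE from band 4 (720 nm) by default; band 5 (750 nm)
  is selectable, since which red-edge channel a camera's "red edge" means
  varies by instrument.
* Zero denominators raise a `SingularIndexError` naming the index —
  no silent NaNs.

Ratio-only indices (MSR, GNDVI, MTCI, CI) are invariant to a common
scaling of all bands; indices with additive constants (SAVI, OSAVI,
MSAVI, EVI) are not.  Both directions are asserted in tests.

## 4. GLCM texture features

Eight co-occurrence measures per band (formulas in `glcm_texture.py`,
natural-log entropy, `0·ln 0 ≡ 0`).  Numerical conventions:

* **Quantization**: 64 linear bins over the band's *scene-wide* min–max
  by default.  The alternative (`quantization="region"`) bins each region
  over its own range, which normalizes local contrast away — regions then
  differ only in the *shape* of their spatial variation, not its
  amplitude.  Since the generator plants amplitude signal, and full-band
  binning is the usual behaviour of image-processing toolchains,
  scene-wide is the default; the switch exists because vendor defaults
  are often undocumented and the two give different feature values.
* **Offset**: displacement (dr, dc), default (1, 1) — the common "shift
  X=1, Y=1" default of remote-sensing texture tools; (0, 1) and any other
  sub-window displacement are configurable.  Feature values differ across
  offsets, so the choice is recorded in the run manifest.
* **Symmetric** GLCM by default (each pair counted both directions);
  asymmetric by flag.
* **Edge handling**: a window center contributes only if its full
  window lies inside the region (and contains no masked pixels).  No
  padding — no fabricated pixels enter the statistics.  A region smaller
  than the window raises, naming the region.
* **Degenerate windows**: a constant window has MEA = 0 (its only level),
  VAR = CON = DIS = ENT = 0, HOM = SEM = 1, and an *undefined* correlation.
  COR is returned as a 0 sentinel at window level but excluded from the
  regional COR average; a fully constant region reports COR = 0.
* The regional feature is the average of window values over valid centers
  (COR over defined centers), giving the 48-vector
  Mean1..Correlation1, …, Mean6..Correlation6 (band-major).

The implementation is checked two ways: against a naive double-loop
pair-enumeration oracle (to 1e-12, also rerun by the acceptance script)
and against scikit-image's `graycomatrix` for the co-occurrence counts.

## 5. Texture-index search

All ordered pairs (i, j), i ≠ j, of the 48 features are searched per
family; the diagonal is excluded (RTI ≡ 1, NDTI ≡ 0 — degenerate).
Pairs hitting a zero denominator at any sample are skipped and counted,
not fatal; only an entirely singular family errors.  Ranking is by |r|
with sign retained; exact ties resolve to the first pair in band-major
(row-major) order, making output deterministic.  The DTI/NDTI matrices
are antisymmetric and ATI/RATI symmetric by construction — asserted on
random data.

Selecting the maximum of ~2.2k correlated statistics inflates |r|, and the
naive p-value of the winner is optimistic.  An optional permutation test
(seeded, default 999 draws when enabled) recomputes the family-wise
maximum under moisture permutation and reports
`(1 + #{max_perm ≥ max_obs}) / (n_perm + 1)`.  It is off by default to
mirror the published workflow this package follows.

By default the search runs on the **training split only**, so no
validation moisture leaks into feature construction; the winning pairs are
then materialized as index columns for all samples.  `search_on_all_samples=True`
searches on all samples instead, as published workflows evidently do.

## 6. Screening and combinations

Every candidate feature is Pearson-correlated with moisture; the two-sided
p-value comes from `t = r sqrt((n−2)/(1−r²))` on n−2 df (scipy's exact
equivalent for scalar calls, the t-formula vectorized for large tables —
they agree to 1e-12).  Features with p < α (default 0.05) survive.  No
multiple-testing correction by default, matching common practice in this
workflow; Benjamini–Hochberg is available.  Constant columns screen as
r = NaN / not significant rather than erroring — a fully deterministic
scene legitimately produces constant texture columns.  Under a null
simulation the significant fraction at α = 0.05 is 0.05 ± 0.01 (checked
at 10⁴ features).

Combinations: ① significant vegetation indices, ② significant texture
features, ③ significant best-pair texture indices, ④ the ordered union.
An empty combination warns at screening and is refused (skipped with a
warning) by the model stage.

## 7. Models

54 samples split 2:1 (36 train / 18 validation), random, unstratified,
seeded.  Inputs are z-scored with training-set statistics before the two
neural models (bounded activations need comparable scales; the tree model
sees raw features); the LM network also z-scores the target and unscales
predictions.

* **ELM**: H = sigmoid(XW + b), W, b ~ U[−1, 1], 60 hidden neurons,
  output weights `pinv(H) y` (minimum-norm least squares — rank
  deficiency never crashes).  50 restarts; the draw with the lowest
  *training* RMSE is kept — validation data are never consulted, so with
  60 neurons ≥ 36 training rows every restart interpolates and the
  selection cannot prevent poor generalization on noisy inputs.  That
  behaviour is real and reported, not patched: it is why the model
  comparison ranks the ELM last under noise.
* **XGBoost**: 100 estimators, learning rate 0.03, max depth 5, other
  parameters at library defaults, seeded, single-threaded for exact
  reproducibility.
* **LM backprop network**: ŷ = tanh(XW₁+b₁)w₂+b₂ with 15 hidden units;
  Levenberg–Marquardt on the sum-of-squares loss,
  Δθ = (JᵀJ + μI)⁻¹Jᵀe with analytic Jacobian; μ starts at 1e−3, ×10 on a
  rejected step, ÷10 on acceptance; stop after 1000 epochs, when the SSE
  improvement stays < 1e−8 for 10 accepted epochs, or when μ exceeds
  1e10.  Accepted steps never increase the training SSE (asserted on the
  logged trajectory).  Epoch cap and stopping rule are this package's
  documented defaults; at n = 36 the fit converges in tens of epochs.

Metrics: R² (residual form 1 − SS_res/SS_tot by default; the
explained-variance form Σ(ŷ−ȳ)²/Σ(y−ȳ)², which matches it exactly for
OLS-consistent training fits, is available by flag), RMSE (percentage
points of moisture), MRE (mean *absolute* relative error, %; signed
errors would cancel and make the metric vacuous).  Negative validation R²
is allowed and occurs for badly generalizing models.

## 8. Pipeline, determinism, problem sizes

`RunConfig` bundles all stage parameters; `with_seed(s)` derives every
stage seed from one master seed (scene s, split s+1, ELM s+2, XGBoost s+3,
LM network s+4).  A run writes every intermediate table, `results.csv`,
`predictions.csv`, optional heatmaps/scatters, and a `manifest.json`
(config + library versions); two runs from the same config produce
byte-identical results tables, and each CLI stage re-runs standalone from
the previous stage's files.

Default problem sizes were chosen for statistically stable checks on a
desktop: 54 plots of 24 × 24 px (≈ 105k GLCM windows per scene, a few
seconds), 10⁴ features for the screening null, 100 replicates for
planted-pair recovery.  Larger rasters only sharpen the GLCM averages.

## Known limitations

* The scene model is stationary Gaussian texture on uniform plots —
  adequate to validate the *estimation machinery*, silent on real canopy
  structure, shadows, soil background and radiometric drift.
* With 54 samples the validation metrics carry large seed-to-seed
  variance; conclusions about model ranking beyond "trees/LM-net ≥ ELM
  under noise" would need repeated splits, which the published workflow
  (and hence the default pipeline) does not do.
* The texture-index search is a max over ~2.2k correlated tests per
  family; its naive p-values overstate significance.  Use the permutation
  option when the selection itself is the claim.
* GLCM features depend materially on quantization range, offset and
  symmetry conventions; cross-study comparisons require matching all
  three (they are recorded in the manifest).
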