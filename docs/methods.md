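# Methods

## The synthetic data model

Real calibration data for this problem — per-sample mean NIR spectra of
intact rice with wet-chemistry prolamin/glutelin reference values — are not
publicly available, so every stage is exercised against a generator that
reproduces the *statistical structure* of such data.

**Contents.** Prolamin and glutelin contents (%, mass fraction of flour) are
drawn from truncated normal distributions by rejection sampling from a
bivariate normal: configured mean/SD per analyte, hard truncation at the
configured min/max, and a latent correlation (default 0.3) between the two
fractions, since both are storage proteins responding to the same agronomic
drivers. Defaults are the published training-set statistics: prolamin
0.70 ± 0.07 % on [0.51, 0.88], glutelin 5.01 ± 0.99 % on [3.43, 7.38].
Truncation slightly biases the realized moments relative to the underlying
normal parameters (noticeably for glutelin, whose bounds are asymmetric at
≈ −1.6 σ/+2.4 σ); at n = 192 the bias is well inside three standard errors
and is accepted rather than corrected.

**Spectra.** Each spectrum is

    x(λ) = offset + slope·(λ − λ₀) + Σ_analytes c_a · Σ_bands k_{b,a}·G_b(λ) + ε(λ)

with Gaussian band profiles G_b (center, width in nm), per-analyte coupling
coefficients k (absorbance per % content), and i.i.d. Gaussian instrument
noise ε. The default library plants prolamin-coupled bands at 1020 and
1500 nm, glutelin-coupled bands at 1050 and 1480 nm, and a shared band at
1450 nm — inside the N–H second-overtone (1000–1100 nm), N–H first-overtone
(1450–1550 nm) and O–H (≈1450 nm) assignment windows for grain protein.
Couplings are scaled so each analyte contributes a few tenths of an
absorbance unit at typical contents; baseline offset 0.20, slope 10⁻⁴/nm,
noise SD 0.005 AU. Values are "absorbance-like" and unitless: the generator
does not model a specific instrument, scattering, water/starch interferents,
or any nonlinearity, so passing tests demonstrate correctness of the
algorithms, not instrument-level realism.

**A rank caveat that shapes the tests.** With *exactly* zero noise the
centered spectra matrix has rank equal to the number of analytes: every
column is the same two-dimensional content signal re-scaled. Any two
independent columns then predict either content exactly, all candidate
wavelength subsets tie at zero RMSE, and "which wavelengths are selected"
is decided by tie-breaking, not by information content. Recovery tests for
the RMSE-driven selectors therefore use a small noise floor (0.002 AU,
about 1 % of the band signal), which restores identifiability; tests of
single-band correlation structure handle the zero-noise saturation
explicitly.

## Preprocessing

* `trim_bands` is pure slicing (values bit-identical); the study
  configuration drops 13 leading and 11 trailing bands of a 224-band
  acquisition, leaving 200.
* `remove_outliers_plsr` fits one PLSR on **all** samples per analyte and
  flags |residual| > k·SD(residuals), single pass, k = 3 by default. The
  component count is not tuned here (default 10, the midpoint of the 1–20
  calibration range). A residual SD below 10⁻¹⁰ of the target SD is treated
  as a numerically perfect fit and flags nothing. The pipeline removes a
  sample flagged for either analyte from both calibrations, keeping one
  common retained set.
* `split_dataset` shuffles with a seeded generator and assigns contiguous
  blocks; validation and test sizes are floor-proportional and the
  remainder goes to training (288 at 4:1:1 → 192/48/48 exactly). No content
  stratification is applied.

## Wavelength selection

**SPA.** Columns are mean-centered by training means. For every start
column a projection chain is grown: the next column maximizes the residual
norm after orthogonal projection onto the complement of the span of the
chain (ties to the lower index). Every chain prefix with size in
[n_min, n_max] is scored by the validation RMSE of an OLS fit with
intercept on the selected columns; minimal RMSE wins, ties preferring the
smaller subset and then the lexicographically smaller index tuple. If all
chains collapse (numerically dependent columns) before n_min, a selection
error reports the longest chain length reached.

**CARS.** At run i a PLS1 model is fitted on a Monte Carlo subsample
(default 80 % of training rows, drawn without replacement) restricted to
the currently retained columns; its component count (≤ max_components,
default 20) minimizes leave-one-out RMSE on the subsample. Columns are
ranked by |regression coefficient| and competitively reduced to the
schedule count ceil(r_i·p), r_i = a·e^(−k·i) with k = ln(p/2)/(N−1),
a = e^k — all p columns survive run 1, exactly two survive run N. The
reduction draws exactly ceil(r_i·p) columns *without* replacement with
probability proportional to the normalized |coefficient| — a formulation
that makes the retained-count sequence deterministic while keeping the
competitive stochastic character of adaptive reweighted sampling. After all
runs each run's retained set is scored by cross-validated (default
leave-one-out) PLSR RMSE on the full training set; minimal RMSE wins, ties
preferring fewer columns, then the earlier run. The study-scale
configuration uses 5000 runs; tests use 50, which already reaches the
2-column floor (the schedule, not the run count, controls the endpoint).

A custom nested-components PLS1 (NIPALS) computes coefficients for all
component counts 1..A in a single pass, making leave-one-out affordable
inside the Monte Carlo loop; it is verified against
`sklearn.cross_decomposition.PLSRegression` in the test suite.

**Grad-CAM++.** For a CNN with scalar output Y and conv-layer feature maps
A (channels × positions), g = ∂Y/∂A from an exact backward pass,

    α = g² / (2g² + Σ_pos(A)·g³)   (0/0 := 0)
    w_k = Σ_pos α·relu(g),  M = relu(Σ_k w_k·A_k)

The second/third derivatives of a ReLU network's scalar output vanish
almost everywhere, so the standard surrogate replaces them with elementwise
g² and g³ (exact under an exponential transform of the score); the
regression output is used directly, with relu on g keeping
content-increasing evidence (|g| available by flag). Maps are linearly
interpolated from layer positions to the wavelength grid (nearest-neighbor
by flag) and min–max normalized per sample (all-zero maps stay zero; a
constant positive map normalizes to 1); the profile reports the
per-wavelength mean and sample SD across the chosen split. Per-sample
normalization before averaging is the default; normalizing the pooled set
is a config option. Note that the normalized map is *not* exactly invariant
to re-scaling the network's final layer: α = 1/(2 + ΣA·g) is not
0-homogeneous in g. Min–max normalization does cancel any positive constant
multiplying the finished map, and that weaker property is what the suite
asserts.

`threshold_select` keeps wavelengths whose mean weight strictly exceeds the
threshold (0.6/0.7 in the study configuration); raising the threshold can
only shrink the selection, and an empty result is valid and flagged.

## Calibration models

* **PLSR** — `sklearn` NIPALS, mean-centered only; latent-factor count
  chosen from 1–20 by 10-fold CV RMSE, refit on all training rows. With as
  many factors as full-rank columns it reproduces the OLS solution (tested
  against the normal equations).
* **SVR** — ε-SVR in a StandardScaler pipeline; exhaustive grid over
  kernel ∈ {linear, rbf, poly}, C ∈ 10⁻⁷…10⁷ (15 log-spaced points),
  γ ∈ {scale, auto}, scored by 10-fold CV RMSE (winner verified against a
  brute-force loop).
* **BPNN** — one hidden layer (default 1024 ReLU units), MSE loss, Adam,
  batch 16, learning rate 10⁻³, default 5000 epochs. Initialization is
  Glorot-uniform: for this shallow architecture He scaling over-weights the
  first layer and memorizes small calibration sets (validation r ≈ 0.95 on
  a noiseless linear target where the Glorot-initialized network and the
  sklearn reference both reach ≥ 0.99).
* **CNN** — conv(16, k7) → pool2 → conv(32, k5) → pool2 → fc 256 → 64 → 1,
  all ReLU; Adam, batch 128, learning rate 10⁻³, default 500 epochs. The
  published architecture details are not printed, so the layer sizes are a
  documented, configurable choice. The second conv layer is addressable by
  name for saliency. The pipeline shrinks the kernels ((5,3) → (3,3) →
  (2,2)) when a small wavelength selection falls below the stack's
  receptive field.
* Both networks standardize the target and keep the best of n_restarts ≥ 5
  seeded runs by validation RMSE (restart log stored in metadata; tests use
  1–2 restarts). Feature scaling differs deliberately: the BPNN
  standardizes each band; the CNN centers per band but divides by a single
  global factor (the mean per-band SD), because per-band scaling amplifies
  noise in signal-free regions to unit variance, degrading both the conv
  fit and the spatial meaning of its activation maps.

All training is seeded and bit-reproducible; everything runs on CPU in
NumPy (no deep-learning framework dependency).

## Evaluation

Pearson r and RMSE per split; zero-variance inputs raise a metric error
rather than reporting r = 0. Rendered tables round to 3 decimals; JSON
artifacts keep full precision. `scatter_data` emits measured/predicted
pairs with an OLS fit line (plot-ready; no figure rendering).
`reduction_report` is the pure identity 100·(1 − n_selected/n_full): 98 of
200 wavelengths → 51 %, 24 of 200 → 88 %.

## Pipeline

`run_experiment` executes generate/ingest → trim → outlier screen → split →
select → fit → interpret → evaluate for the full factorial {full, SPA,
CARS, Grad-CAM++@thresholds} × {PLSR, SVR, BPNN, CNN} × {prolamin,
glutelin} and writes a manifest with stage order, seeds and SHA-256 hashes
of every artifact; reruns of the same config produce identical hashes (wall
times are logged outside the manifest). Grad-CAM++ profiles are computed
from the full-spectra CNN on the test split's spectra, mirroring the study
protocol; because selecting features from test data is a leakage risk, the
manifest flags this data flow and `gradcam_split: validation` switches to
the validation split. No stage reads test-split targets before final
evaluation.

## Problem sizes used in the tests

The suite runs everything at desk scale as the package's own default test
sizes: 60–80 bands/24–72 samples for unit tests; the recovery study at the
study's geometry (200 bands, 288 samples, 4:1:1 split) with 50 CARS runs,
500 training epochs and 1–2 restarts. A planted band counts as recovered
when a selected wavelength lies within one band width (Gaussian σ) of its
center — adjacent columns within a band are near-collinear carriers of the
same feature — and recovery is pooled over each analyte's coupled bands.

## Known limitations

* The generator is linear in content with Gaussian i.i.d. noise; real
  husk-on seed spectra add scattering, moisture/starch interference and
  band nonlinearity. Passing recovery tests show the algorithms work, not
  that field performance would match.
* The published r/RMSE tables of the original study cannot be reproduced
  without its (unreleased) 288-sample dataset and are not targets here.
* SPA scores subsets on the held-out validation split; an internal-CV
  variant of the inner criterion is not implemented.
* The outlier screen's component count and threshold are assumptions (the
  source protocol is unstated); the 302 → 288 sample reduction is not
  treated as reproducible.
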