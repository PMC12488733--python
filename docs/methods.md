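# Methods note

This note records the modelling choices, parameters, numerical conventions,
the scope of the synthetic data generator, and known limitations. It makes
no empirical claims beyond what the test-suite and `scripts/acceptance.py`
compute.

## Measurement model

A push-broom Vis-NIR imager yields a rows × cols × 360 intensity cube over
395–1008 nm (band centers evenly spaced, ≈1.71 nm apart). Raw counts are
converted to relative reflectance against a white reference panel:

    R[p, b] = (I_raw[p, b] − I_dark[b]) / (I_white[b] − I_dark[b])

clipped to [0, 1.1]; the 10 % headroom accommodates specular highlights on
glossy fruit. Dark current defaults to zero (preheated instrument) but a
measured dark frame is accepted.

## ROI segmentation

Fruit pixels are separated from the dark background by a two-band contrast
score, reflectance(800 nm) − reflectance(450 nm), followed by Otsu
thresholding, retention of the largest 8-connected component, and hole
filling. The component boundary is traced at sub-pixel resolution,
parameterized by normalized arc length and fitted by a closed uniform
periodic cubic B-spline (40 control points, linear least squares with
coefficients identified modulo the control count). The smoothed contour is
rasterized back to a mask and the per-band mean over masked pixels is the
fruit's spectrum. For masks too small to support the spline fit the raw
component mask is used unchanged.

## Preprocessing

Savitzky-Golay smoothing (default window 11 bands, polynomial order 2) is
applied along the band axis; edges use the polynomial fitted to the nearest
full window so the band count is preserved. No scatter correction (SNV,
MSC) is applied: the networks standardize inputs per band and use batch
normalization internally.

## SPA wavelength selection

The successive projections algorithm runs in three phases on the training
partition only:

1. Columns are standardized (population SD). From every candidate start
   band a greedy chain grows: all unselected columns are projected onto the
   orthogonal complement of the selected span (Gram-Schmidt deflation) and
   the largest-residual-norm column is appended. Chains truncate if the
   residual space is exhausted, so exact duplicates can never recur.
2. Every chain prefix with size in [k_min, k_max] is scored by PRESS — the
   squared prediction error of an intercept OLS fit, evaluated on a seeded
   30 % validation split held out of the calibration data. The globally
   best prefix wins.
3. Winning variables are ranked by relevance |b_j|·s_j and the smallest
   top-ranked prefix whose PRESS ratio to the global minimum stays below
   the one-sided critical value F(α = 0.25; n_val, n_val) is returned.

Defaults: k_min = 5, k_max = full band count. Tests and the acceptance
report use k_max = 30: at n = 300 the winning subsets are far smaller than
30 bands and full-depth all-start chains at 360 bands cost minutes per
seed without changing the selection.

## Regression networks

Spectra enter as n-band vectors reshaped to an n × 1 × 1 pseudo-image; one
network regresses one analyte.

* **cnn** — conv(8 filters, 3×1, same padding) → batch norm → ReLU →
  maxpool 2×1 → conv(32) → BN → ReLU → pool → dropout 0.4 → dense 32 →
  dense 1. Two floor-division pooling stages require n ≥ 4 input bands.
* **cnn_bigru** — a conv branch (16 filters, BN, ReLU, 3×1 pool, dense 25)
  in parallel with two 35-unit GRUs reading the band sequence forward and
  reversed; final hidden states concatenate with the conv features to a
  95-wide merged vector feeding dense 1.
* **cnn_bigru_attention** — the same trunk with single-head scaled
  dot-product self-attention over the 95 merged features (each feature a
  scalar token affinely mapped to 50-dimensional keys/queries/values,
  scores softmaxed at scale 1/√50, attended values mean-pooled) before
  dense(50 → 1).

Training: Adam (β₁ = 0.9, β₂ = 0.999) on mean-squared error, batch 16,
coupled L2 on weight matrices (biases and batch-norm parameters excluded).
The cnn trains 500 epochs at learning rate 1e-3; the hybrids 1000 epochs
from 1e-2 with a single ×0.1 step at epoch 700. All three use L2 = 0.01:
at a few hundred training samples the hybrids' ~13k parameters overfit
under weaker decay.
Inputs are standardized per band and the target to zero mean/unit SD, both
frozen from the training partition. Layer plans carry hand-summed parameter
counts that the constructed network must match exactly. All arithmetic runs
in float64 on a small in-repo reverse-mode autograd engine
(convolution via im2col, pooling with argmax routing, GRU as unrolled
tensor ops); gradients are finite-difference tested. A fixed seed gives
bit-identical weights.

## Evaluation

R² = 1 − SSE/SST, RMSE = √(SSE/n), RPD = SD(y)/RMSE. RPD uses the sample
SD (ddof = 1) by default; with the population convention RPD ≡ 1/√(1−R²),
an identity the tests assert. RPD > 2.0 reads "good", ≤ 1.4 "weak".
Datasets split 7:3 by a seeded permutation (train size = round(0.7 n)),
optionally stratified by cultivar. External sets are scored by the frozen
model; percent degradation 100·(internal − external)/internal is rounded
half-up to two decimals (decimal arithmetic, not binary float rounding).

## Synthetic generator: scope

No public dataset exists for this instrument/fruit combination, so the
generator supplies data with the statistical structure the pipeline
assumes — it is a test harness, not a claim about any orchard.

* Analytes are drawn uniformly from the library ranges: VC 1.08–3.27
  mg/100 g, SSC 8.48–11.92 %, SP 0.32–0.51 mg/g.
* The baseline is a logistic pigment shoulder below ~560 nm, a chlorophyll
  dip at 680 nm and a water feature at 970 nm, with cultivar-level pigment
  modulation (6 cultivars).
* Analyte-linked Gaussian absorption features: VC at 409/577/679/700/757 nm
  (σ = 5 nm), SP at 403/430/551/617/846 nm (σ = 5), SSC as broad features
  at 740/800/860/920 nm (σ = 25). Feature depth is proportional to the
  range-normalized analyte plus independent per-feature jitter
  (SD 0.12) — the sub-component concentrations an analyte is read through
  covary imperfectly, so each planted band carries partially independent
  information.
* A smooth rank-3 per-sample baseline field (Legendre offset/tilt/
  curvature, RMS 0.02) models fruit-to-fruit size and scattering
  variation, making background bands mutually correlated rather than
  independent noise.
* Band-wise Gaussian noise SD 0.005; reflectance clipped to [0, 1].
* Cube scenes place a low-order perturbed ellipse of fruit spectrum under
  a smooth ±10 % spatial gain on a dark NIR-poor background.

Consequence of the nuisance terms: the textbook single-band correlation
(|corr| ≥ 0.9 between a planted band and its analyte) holds with jitter and
the baseline field disabled, and is tested that way; under full defaults
single-band correlations are deliberately weaker, which is what makes
multivariate selection necessary.

## Numerical conventions

* float64 throughout; ENVI files written as little-endian float32.
* Population SD (ddof = 0) for standardization inside SPA and the training
  loop; sample SD (ddof = 1) for the default RPD.
* Seeds: `numpy.random.default_rng`; every stochastic routine takes an
  explicit seed and is reproducible bit-for-bit.
* Degradation percentages use `decimal` half-up quantization to 2 places.

## Limitations

* The networks are desk-scale: the engine is pure numpy on one CPU, so
  full-spectrum (360-band) BiGRU training is slow; tests and the
  acceptance report train on SPA-selected bands (6–15 bands) and the
  acceptance script shortens the hybrid schedule to 600 epochs with the
  ×0.1 step at the same 7/10 mark.
* Synthetic spectra are additive Gaussian-feature models; they do not
  emulate multiplicative scatter, temperature-dependent water shifts, or
  detector nonlinearity (a multiplicative/additive scatter hook exists but
  is off by default).
* Segmentation assumes a single fruit per frame on a dark background.
* Hybrid-network L2 and the exact attention head geometry follow the
  package's own conventions stated above; alternative readings of the
  published architectures exist.
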