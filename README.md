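# pomonet

Vis-NIR hyperspectral pipeline for non-destructive fruit quality prediction:
from raw reflectance cubes to per-analyte regression models for vitamin C
(VC, mg/100 g), soluble solids content (SSC, %) and soluble protein
(SP, mg/g).

The pipeline mirrors standard hyperspectral calibration practice for apples
measured over 395–1008 nm (360 contiguous bands):

1. **Cube I/O and white-reference correction** (`pomonet.cube_io`) — ENVI
   header/binary pairs (BIL/BIP/BSQ), reflectance =
   (raw − dark) / (white − dark).
2. **ROI segmentation** (`pomonet.roi`) — two-band spectral contrast, Otsu
   threshold, largest connected component, periodic B-spline contour
   smoothing, mean fruit spectrum.
3. **Savitzky-Golay smoothing** (`pomonet.preprocessing`) — local polynomial
   least squares along the band axis (default window 11, order 2).
4. **SPA wavelength selection** (`pomonet.spa`) — successive projections
   algorithm: orthogonal-projection chains, validation-set PRESS over chain
   prefixes, relevance ranking with F-test pruning.
5. **Regression networks** (`pomonet.models`) — three architectures: a 1-D
   CNN, a CNN-BiGRU hybrid (conv branch ∥ bidirectional GRU, 25 + 70 = 95
   merged features) and CNN-BiGRU-Attention (single-head self-attention over
   the merged features). Implemented on a small in-repo reverse-mode autograd
   engine (`pomonet.autograd`, `pomonet.nn`) with Adam, L2 and a step
   learning-rate schedule; training is bit-reproducible from a seed.
6. **Evaluation** (`pomonet.evaluation`) — R², RMSE, RPD (with the
   population-SD identity RPD = 1/√(1−R²)), seeded 7:3 splits, external
   validation and percent degradation.
7. **Synthetic data** (`pomonet.synthetic`) — a seeded optical forward model
   (pigment/chlorophyll/water baseline, analyte-linked Gaussian absorption
   features, smooth per-sample baseline field, band noise) for spectra and
   whole cubes, used by the test-suite and the acceptance report.

## Worked example

A statsmodels-style Model/Results surface wraps the whole chain. The
snippet below generates a labelled synthetic set, selects wavelengths with
SPA on the training split only, trains the CNN and prints the summary —
output shown exactly as produced:

```python
from pomonet import (SpectralRegression, SpaConfig, TrainConfig,
                     WavelengthGrid, generate_dataset)

grid = WavelengthGrid.default(n_bands=120)
dataset = generate_dataset(200, grid=grid, seed=7)

model = SpectralRegression(
    dataset.analyte("sp"), dataset.X,
    wavelengths=grid.values,
    architecture="cnn",
    preprocessing="sg",
    selection="spa",
    spa_config=SpaConfig(k_min=5, k_max=20),
)
results = model.fit(train_config=TrainConfig.for_kind("cnn", epochs=200),
                    split_seed=0, seed=0)
print(results.summary())
```

```
Spectral analyte regression
============================================================
architecture:     cnn
preprocessing:    SG
selection:        spa (5 bands)
input bands:      5
split:            140 train / 60 test (seed 0)
parameters:       2001
------------------------------------------------------------
split         R2      RMSE        SD     RPD  band
train      0.907    0.0156    0.0514   3.291  good
test       0.757    0.0232    0.0475   2.045  good
------------------------------------------------------------
selected wavelengths (nm): 416, 519, 617, 694, 853
============================================================
```

External sets (e.g. a later harvest) are scored with the frozen model —
never refitted:

```python
external = generate_dataset(60, grid=grid, seed=99)
report = results.evaluate_external(external.X, external.analyte("sp"))
print(results.degradation_vs_external(report))  # {'r2_pct': ..., 'rpd_pct': ...}
```

## Command line

Every stage is also a `pomonet` subcommand:

```bash
pomonet simulate --n 300 --seed 0            # labelled synthetic spectra
pomonet make-cube --rows 64 --cols 64        # synthetic ENVI fruit cube
pomonet segment cube.hdr                     # ROI mask + mean spectrum
pomonet preprocess spectra.csv               # Savitzky-Golay smoothing
pomonet select spectra.csv analytes.csv --analyte sp
pomonet train spectra.csv analytes.csv --architecture cnn_bigru_attention \
    --selection spa
pomonet run config.yaml                      # full declarative pipeline run
```

`pomonet run` consumes a YAML `RunConfig` (data source, input configuration
RAW / SG / SPA+RAW / SPA+SG, architecture, seeds) and writes a
self-contained output directory: `metrics.json`, `metrics.csv`, `spa.json`,
`model.zip`, `loss_curve.csv`, `provenance.json`.

## Reproducing results

The test suite (unit, property and acceptance tests) runs with:

```bash
python -m pytest -q tests/
```

The acceptance report recomputes the package's headline quantities — the
published degradation worked examples, SPA planted-band recovery,
segmentation IoU and per-analyte network test metrics — from a single seed:

```bash
python scripts/acceptance.py --seed 1 --out report.json
```

Both are deterministic given the seed. See `docs/methods.md` for the model
equations, the synthetic generator's scope, numerical conventions and known
limitations.
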