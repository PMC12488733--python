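"""Synthetic Vis-NIR apple spectra, analyte panels, and hyperspectral cubes.

No public reference dataset exists for this instrument/fruit combination, so
the generator produces data with the statistical structure the pipeline
assumes: smooth reflectance baselines in [0, 1] over 395-1008 nm with pigment
absorption below ~675 nm, a chlorophyll dip near 680 nm and a water feature
near 970 nm; Beer-Lambert-style additive Gaussian absorption features linked
linearly to the three analytes; band-wise Gaussian noise; and cultivar-level
modulation of pigment depth.  Analyte links follow the wavelength assignments
established for this fruit: vitamin C near 409/577/679/700/757 nm, soluble
protein at 403/430/551/617/846 nm, soluble solids as broad features in
700-950 nm.  Everything is reproducible from (seed, config).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pomonet.cube_io import HyperCube, WavelengthGrid
from pomonet.roi import RoiMask

__all__ = [
    "ANALYTE_RANGES",
    "AbsorptionFeature",
    "OpticalModel",
    "SpectralDataset",
    "generate_dataset",
    "generate_cube",
]

#: Printed analyte ranges across the sample library:
#: vitamin C in mg/100 g, soluble solids in percent, soluble protein in mg/g.
ANALYTE_RANGES = {
    "vc": (1.08, 3.27),
    "ssc": (8.48, 11.92),
    "sp": (0.32, 0.51),
}

#: Planted feature wavelengths (nm) per analyte.
VC_BANDS_NM = (409.0, 577.0, 679.0, 700.0, 757.0)
SP_BANDS_NM = (403.0, 430.0, 551.0, 617.0, 846.0)
SSC_BANDS_NM = (740.0, 800.0, 860.0, 920.0)

CULTIVARS = ("AKS", "SPFS", "YTFS", "YT", "GG", "HN")


@dataclass(frozen=True)
class AbsorptionFeature:
    """One Gaussian absorption component tied to an analyte."""

    center_nm: float
    width_nm: float      # Gaussian sigma
    analyte: str         # 'vc' | 'ssc' | 'sp'
    strength: float      # reflectance depth at unit (range-normalized) analyte


def _default_features() -> tuple[AbsorptionFeature, ...]:
    features = [AbsorptionFeature(c, 5.0, "vc", 0.05) for c in VC_BANDS_NM]
    features += [AbsorptionFeature(c, 5.0, "sp", 0.08) for c in SP_BANDS_NM]
    features += [AbsorptionFeature(c, 25.0, "ssc", 0.07) for c in SSC_BANDS_NM]
    return tuple(features)


@dataclass(frozen=True)
class OpticalModel:
    """Forward model from analyte panel to reflectance spectrum.

    ``noise_sd`` is band-wise Gaussian reflectance noise (default 0.005);
    ``scatter`` optionally applies a per-sample multiplicative/additive
    distortion pair (off by default, available for stress-testing smoothing);
    ``cultivar_pigment_sd`` scales the depth of the visible pigment shoulder
    per cultivar.

    Two structural terms give the spectra the statistical texture of real
    fruit measurements.  ``feature_jitter_sd`` perturbs each absorption
    feature's depth independently around its analyte-proportional value
    (chemically: the bond overtones an analyte is read through belong to
    sub-components whose concentrations covary imperfectly), so every planted
    band carries partially independent information about its analyte.
    ``sample_baseline_sd`` adds a smooth low-rank per-sample baseline field
    (fruit-to-fruit size/scattering variation), so background bands are
    mutually correlated rather than independent noise.
    """

    features: tuple[AbsorptionFeature, ...] = field(
        default_factory=_default_features)
    noise_sd: float = 0.005
    scatter: tuple[float, float] | None = None  # (mult_sd, add_sd)
    baseline_level: float = 0.78
    pigment_depth: float = 0.30
    chlorophyll_depth: float = 0.08
    water_depth: float = 0.10
    cultivar_pigment_sd: float = 0.08
    feature_jitter_sd: float = 0.12       # fraction of the analyte range
    sample_baseline_sd: float = 0.02      # reflectance units, RMS per band
    n_baseline_modes: int = 3             # rank of the smooth sample field

    def baseline(self, wavelengths: np.ndarray,
                 pigment_factor: float = 1.0) -> np.ndarray:
        """Smooth cultivar-level reflectance curve."""
        pigment = 1.0 / (1.0 + np.exp((wavelengths - 560.0) / 60.0))
        chlorophyll = np.exp(-0.5 * ((wavelengths - 680.0) / 12.0) ** 2)
        water = np.exp(-0.5 * ((wavelengths - 970.0) / 25.0) ** 2)
        return (self.baseline_level
                - self.pigment_depth * pigment_factor * pigment
                - self.chlorophyll_depth * chlorophyll
                - self.water_depth * water)


@dataclass
class SpectralDataset:
    """Samples x wavelengths reflectance with per-sample analytes and labels."""

    X: np.ndarray
    panel: pd.DataFrame          # columns vc, ssc, sp
    cultivar: np.ndarray
    grid: WavelengthGrid

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    def analyte(self, name: str) -> np.ndarray:
        return self.panel[name].to_numpy()

    def to_csv(self, spectra_path: str | Path, analyte_path: str | Path) -> None:
        cols = [f"{w:.3f}" for w in self.grid.values]
        spectra = pd.DataFrame(self.X, columns=cols)
        spectra.insert(0, "sample_id", np.arange(self.n_samples))
        spectra.to_csv(spectra_path, index=False)
        panel = self.panel.copy()
        panel.insert(0, "sample_id", np.arange(self.n_samples))
        panel["cultivar"] = self.cultivar
        panel.to_csv(analyte_path, index=False)

    @classmethod
    def from_csv(cls, spectra_path: str | Path,
                 analyte_path: str | Path) -> "SpectralDataset":
        spectra = pd.read_csv(spectra_path)
        panel = pd.read_csv(analyte_path)
        wavelengths = np.array([float(c) for c in spectra.columns[1:]])
        cultivar = (panel.pop("cultivar").to_numpy()
                    if "cultivar" in panel else
                    np.array(["unknown"] * len(panel)))
        panel = panel.drop(columns=["sample_id"], errors="ignore")
        return cls(spectra.iloc[:, 1:].to_numpy(float), panel,
                   cultivar, WavelengthGrid(wavelengths))


def _normalized_panel(panel: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for name, (lo, hi) in ANALYTE_RANGES.items():
        out[name] = (panel[name] - lo) / (hi - lo)
    return pd.DataFrame(out)


def _spectra_from_panel(panel: pd.DataFrame, pigment_factors: np.ndarray,
                        grid: WavelengthGrid, model: OpticalModel,
                        rng: np.random.Generator) -> np.ndarray:
    wavelengths = grid.values
    lo, hi = wavelengths[0], wavelengths[-1]
    for feature in model.features:
        if not (lo <= feature.center_nm <= hi):
            raise ValueError(
                f"feature center {feature.center_nm} nm outside grid range")

    n = len(panel)
    norm = _normalized_panel(panel)
    spectra = np.empty((n, grid.count))
    for i in range(n):
        spectra[i] = model.baseline(wavelengths, pigment_factors[i])
    for feature in model.features:
        shape = np.exp(-0.5 * ((wavelengths - feature.center_nm)
                               / feature.width_nm) ** 2)
        depth = norm[feature.analyte].to_numpy()
        if model.feature_jitter_sd > 0:
            depth = depth + rng.normal(0.0, model.feature_jitter_sd, size=n)
        spectra -= feature.strength * depth[:, None] * shape
    if model.sample_baseline_sd > 0 and model.n_baseline_modes > 0:
        x = (2.0 * (wavelengths - wavelengths[0])
             / (wavelengths[-1] - wavelengths[0]) - 1.0)
        modes = np.polynomial.legendre.legvander(x, model.n_baseline_modes - 1)
        modes /= np.sqrt((modes ** 2).mean(axis=0))  # unit RMS per mode
        coeffs = rng.normal(0.0, 1.0, size=(n, model.n_baseline_modes))
        spectra += (model.sample_baseline_sd
                    / np.sqrt(model.n_baseline_modes)) * coeffs @ modes.T
    if model.scatter is not None:
        mult_sd, add_sd = model.scatter
        spectra *= 1.0 + rng.normal(0.0, mult_sd, size=(n, 1))
        spectra += rng.normal(0.0, add_sd, size=(n, 1))
    if model.noise_sd > 0:
        spectra += rng.normal(0.0, model.noise_sd, size=spectra.shape)
    return np.clip(spectra, 0.0, 1.0)


def generate_dataset(n: int, grid: WavelengthGrid | None = None,
                     model: OpticalModel = OpticalModel(),
                     seed: int = 0) -> SpectralDataset:
    """Generate ``n`` labelled spectra.

    Analytes are drawn uniformly from the printed ranges; each sample gets a
    cultivar label whose pigment-depth factor modulates the visible baseline.
    """
    if n < 10:
        raise ValueError("need n >= 10 samples")
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(seed)

    panel = pd.DataFrame({
        name: rng.uniform(lo, hi, size=n)
        for name, (lo, hi) in ANALYTE_RANGES.items()
    })
    cultivar_idx = rng.integers(0, len(CULTIVARS), size=n)
    cultivar_factor = 1.0 + model.cultivar_pigment_sd * np.linspace(
        -1.0, 1.0, len(CULTIVARS))
    pigment_factors = cultivar_factor[cultivar_idx]

    X = _spectra_from_panel(panel, pigment_factors, grid, model, rng)
    return SpectralDataset(X=X, panel=panel,
                           cultivar=np.array(CULTIVARS)[cultivar_idx],
                           grid=grid)


# --------------------------------------------------------------------------
# Synthetic cubes for the segmentation chain
# --------------------------------------------------------------------------

def generate_cube(rows: int, cols: int, grid: WavelengthGrid | None = None,
                  model: OpticalModel = OpticalModel(), seed: int = 0,
                  gain_amplitude: float = 0.1,
                  ) -> tuple[HyperCube, RoiMask, pd.DataFrame]:
    """One synthetic fruit scene: cube, ground-truth mask, analyte panel.

    The fruit is an ellipse with low-order boundary perturbation carrying a
    single generated spectrum under a smooth spatial gain in
    [1 - amplitude, 1 + amplitude]; the background is dark with low NIR
    reflectance, so the NIR-minus-blue contrast separates the two.
    """
    grid = grid or WavelengthGrid.default()
    rng = np.random.default_rng(seed)

    # fruit geometry: perturbed ellipse
    cy, cx = rows / 2.0, cols / 2.0
    base_ry = 0.32 * rows
    base_rx = 0.32 * cols
    if min(base_ry, base_rx) < 3:
        raise ValueError("frame too small for a fruit ellipse")
    amp = rng.uniform(0.02, 0.06, size=3)
    phase = rng.uniform(0, 2 * np.pi, size=3)

    yy, xx = np.mgrid[0:rows, 0:cols]
    theta = np.arctan2((yy - cy) / base_ry, (xx - cx) / base_rx)
    wobble = 1.0 + sum(a * np.sin((k + 2) * theta + p)
                       for k, (a, p) in enumerate(zip(amp, phase)))
    radial = np.sqrt(((yy - cy) / base_ry) ** 2 + ((xx - cx) / base_rx) ** 2)
    mask = radial <= wobble

    edge = np.zeros((rows, cols), dtype=bool)
    edge[:2, :] = edge[-2:, :] = edge[:, :2] = edge[:, -2:] = True
    if (mask & edge).any():
        raise ValueError("fruit does not fit inside the frame with 2-px margin")

    # fruit spectrum and analytes (single-sample draw)
    panel = pd.DataFrame({
        name: [rng.uniform(lo, hi)] for name, (lo, hi) in ANALYTE_RANGES.items()
    })
    fruit_spectrum = _spectra_from_panel(
        panel, np.ones(1), grid, model, rng)[0]

    # smooth spatial gain in [1-a, 1+a]
    gy = np.sin(2 * np.pi * yy / rows + rng.uniform(0, 2 * np.pi))
    gx = np.cos(2 * np.pi * xx / cols + rng.uniform(0, 2 * np.pi))
    gain = 1.0 + gain_amplitude * 0.5 * (gy + gx)

    # dark background, NIR-poor so fruit/background contrast is positive
    wavelengths = grid.values
    bg_spectrum = 0.06 - 0.03 * (wavelengths - wavelengths[0]) / (
        wavelengths[-1] - wavelengths[0])

    data = np.empty((rows, cols, grid.count))
    data[:] = bg_spectrum
    data[mask] = gain[mask, None] * fruit_spectrum
    if model.noise_sd > 0:
        data += rng.normal(0.0, model.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.0)

    cube = HyperCube(data, grid, kind="reflectance")
    return cube, RoiMask(mask), panel
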