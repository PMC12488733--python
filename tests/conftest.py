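"""Shared fixtures: small seeded datasets and cubes."""

import numpy as np
import pytest

from pomonet.cube_io import WavelengthGrid
from pomonet.synthetic import OpticalModel, generate_cube, generate_dataset


@pytest.fixture(scope="session")
def small_grid() -> WavelengthGrid:
    """A 60-band grid over the full instrument range (fast tests)."""
    return WavelengthGrid.default(n_bands=60)


@pytest.fixture(scope="session")
def dataset60(small_grid):
    """120 samples on the 60-band grid, seed 0."""
    return generate_dataset(120, grid=small_grid, seed=0)


@pytest.fixture(scope="session")
def cube48():
    """One 48x48 synthetic fruit cube with its ground-truth mask."""
    grid = WavelengthGrid.default(n_bands=40)
    cube, mask, panel = generate_cube(48, 48, grid=grid, seed=0)
    return cube, mask, panel


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 1.0


quiet_optical = OpticalModel(noise_sd=0.0, feature_jitter_sd=0.0,
                             sample_baseline_sd=0.0,
                             cultivar_pigment_sd=0.0)
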