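"""Fruit region-of-interest extraction from reflectance cubes.

The segmentation chain: a two-band spectral-contrast score image (NIR minus
visible reflectance separates fruit tissue from dark background), Otsu
binarization, largest 8-connected component with hole filling, boundary
tracing, periodic B-spline least-squares smoothing of the contour, polygon
rasterization back to a mask, and finally the per-band mean spectrum over the
mask — one spectrum per fruit, the substrate for all downstream modelling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import BSpline
from skimage import measure
from skimage.draw import polygon as draw_polygon
from skimage.filters import threshold_otsu

from pomonet.cube_io import HyperCube

__all__ = [
    "ScoreImage",
    "RoiMask",
    "Contour",
    "enhance",
    "binarize_largest",
    "fit_contour",
    "rasterize_contour",
    "mean_spectrum",
    "segment_cube",
]

#: Default contrast bands: fruit tissue is bright in the NIR (800 nm) and
#: pigment-absorbed in the blue (450 nm); background is dark in both.
DEFAULT_HI_NM = 800.0
DEFAULT_LO_NM = 450.0


@dataclass
class ScoreImage:
    """Per-pixel spectral-contrast scores, same spatial shape as the cube."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("score image must be 2-D")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("score image contains non-finite values")


@dataclass
class RoiMask:
    """Boolean fruit mask with exactly one filled connected component."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class Contour:
    """Closed boundary polyline with its B-spline control polygon."""

    points: np.ndarray          # (m, 2) closed: first row == last row
    control_points: np.ndarray  # (n_control, 2)
    degree: int

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(path, self.points, delimiter=",", header="row,col",
                   comments="")


def enhance(cube: HyperCube, hi_band_nm: float = DEFAULT_HI_NM,
            lo_band_nm: float = DEFAULT_LO_NM) -> ScoreImage:
    """Two-band difference score: reflectance(hi) - reflectance(lo) per pixel."""
    hi = cube.grid.nearest_band(hi_band_nm)
    lo = cube.grid.nearest_band(lo_band_nm)
    return ScoreImage(cube.data[:, :, hi] - cube.data[:, :, lo])


def binarize_largest(score: ScoreImage, min_area: int = 1) -> RoiMask:
    """Otsu threshold, keep the largest 8-connected component, fill holes."""
    values = score.values
    if np.ptp(values) == 0:
        raise ValueError("constant score image: no threshold exists")
    thresh = threshold_otsu(values)
    binary = values > thresh
    if not binary.any():
        raise ValueError("empty foreground after thresholding")
    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    mask = ndimage.binary_fill_holes(labels == keep)
    roi = RoiMask(mask)
    if roi.area < min_area:
        raise ValueError(f"largest component area {roi.area} < min_area {min_area}")
    return roi


# --------------------------------------------------------------------------
# Contour fitting
# --------------------------------------------------------------------------

def _trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed sub-pixel boundary of the mask's single component."""
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("mask has no boundary")
    boundary = max(contours, key=len)
    if not np.allclose(boundary[0], boundary[-1]):
        boundary = np.vstack([boundary, boundary[:1]])
    return boundary


def _periodic_design_matrix(u: np.ndarray, n_control: int,
                            degree: int) -> np.ndarray:
    """Design matrix of a uniform periodic B-spline basis on [0, 1).

    Coefficients are identified modulo ``n_control``, so the matrix has
    ``n_control`` columns and every row sums to 1.
    """
    k = degree
    knots = np.arange(-k, n_control + k + 1, dtype=float) / n_control
    n_basis = n_control + k  # unwrapped basis functions on the extended knots
    design = np.zeros((u.size, n_control))
    for j in range(n_basis):
        coeffs = np.zeros(n_basis)
        coeffs[j] = 1.0
        basis = BSpline(knots, coeffs, k, extrapolate=False)
        column = np.nan_to_num(basis(u))
        design[:, j % n_control] += column
    return design


def fit_contour(mask: RoiMask, n_control: int = 40, degree: int = 3) -> Contour:
    """Least-squares periodic B-spline smoothing of the mask boundary.

    The boundary is traced, parameterized by normalized arc length, fitted by
    a closed uniform B-spline with ``n_control`` control points, and re-sampled
    at the boundary's own resolution.  Smoothing contracts rasterization
    wiggles while preserving the overall fruit silhouette.
    """
    boundary = _trace_boundary(mask.mask)
    pts = boundary[:-1]  # drop the duplicated closing point for fitting
    if pts.shape[0] <= degree + 1:
        raise ValueError(
            f"boundary has only {pts.shape[0]} points; need > degree+1"
        )
    if pts.shape[0] < n_control:
        raise ValueError(
            f"boundary length {pts.shape[0]} < n_control {n_control}"
        )

    seg = np.linalg.norm(np.diff(boundary, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    u = (arc[:-1] / arc[-1]) % 1.0

    design = _periodic_design_matrix(u, n_control, degree)
    control, *_ = np.linalg.lstsq(design, pts, rcond=None)

    u_out = np.linspace(0.0, 1.0, boundary.shape[0], endpoint=False)
    smoothed = _periodic_design_matrix(u_out, n_control, degree) @ control
    smoothed = np.vstack([smoothed, smoothed[:1]])  # close the curve
    return Contour(points=smoothed, control_points=control, degree=degree)


def rasterize_contour(contour: Contour, shape: tuple[int, int]) -> RoiMask:
    """Fill the smoothed contour back into a pixel mask."""
    rr, cc = draw_polygon(contour.points[:, 0], contour.points[:, 1], shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return RoiMask(mask)


def mean_spectrum(cube: HyperCube, roi: RoiMask) -> np.ndarray:
    """Arithmetic mean reflectance over masked pixels, per band."""
    if roi.mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if roi.area == 0:
        raise ValueError("empty ROI mask")
    return cube.data[roi.mask].mean(axis=0)


def segment_cube(cube: HyperCube, hi_band_nm: float = DEFAULT_HI_NM,
                 lo_band_nm: float = DEFAULT_LO_NM, n_control: int = 40,
                 smooth_contour: bool = True) -> tuple[RoiMask, np.ndarray]:
    """Full chain: enhance, binarize, (optionally) B-spline smooth, average.

    Returns the final mask and the mean ROI spectrum.
    """
    score = enhance(cube, hi_band_nm, lo_band_nm)
    roi = binarize_largest(score)
    if smooth_contour:
        try:
            contour = fit_contour(roi, n_control=n_control)
            smoothed = rasterize_contour(contour, roi.mask.shape)
            if smoothed.area > 0:
                roi = smoothed
        except ValueError:
            pass  # tiny ROIs: keep the raw component mask
    return roi, mean_spectrum(cube, roi)


# --------------------------------------------------------------------------
# Export helpers
# --------------------------------------------------------------------------

def mask_to_png(roi: RoiMask, path: str | Path) -> None:
    from imageio import imwrite

    imwrite(Path(path), (roi.mask.astype(np.uint8) * 255))


def mask_to_rle_json(roi: RoiMask, path: str | Path) -> None:
    """Row-major run-length encoding: [start, length] pairs over the flat mask."""
    flat = roi.mask.ravel()
    padded = np.concatenate([[0], flat.astype(np.int8), [0]])
    changes = np.flatnonzero(np.diff(padded))
    starts, ends = changes[::2], changes[1::2]
    runs = [[int(s), int(e - s)] for s, e in zip(starts, ends)]
    Path(path).write_text(json.dumps(
        {"shape": list(roi.mask.shape), "runs": runs}))
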