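"""Savitzky-Golay smoothing of reflectance spectra.

The filter replaces each band with the center value of a least-squares
polynomial fitted inside a sliding window, suppressing high-frequency noise
while preserving peak shape.  It is the only spectral pretreatment applied;
scatter corrections (SNV, MSC) are deliberately omitted because the downstream
networks normalize internally (batch normalization) and extra normalization
risks information loss.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = ["SgConfig", "sg_smooth", "sg_coefficients"]


@dataclass(frozen=True)
class SgConfig:
    """Window width (odd, in bands) and polynomial degree.

    Defaults (window 11, order 2) are the common Vis-NIR choice; both knobs
    are surfaced because the optimal setting is data-dependent.
    """

    window: int = 11
    order: int = 2

    def __post_init__(self) -> None:
        if self.window <= 0 or self.window % 2 == 0:
            raise ValueError(f"window must be odd and positive, got {self.window}")
        if not (0 <= self.order <= self.window - 1):
            raise ValueError(
                f"order must be in [0, window-1], got order={self.order} "
                f"window={self.window}"
            )


def sg_smooth(spectra: np.ndarray, cfg: SgConfig = SgConfig()) -> np.ndarray:
    """Smooth spectra along the band axis.

    Accepts a single spectrum or a samples x bands matrix.  Edges are handled
    by evaluating the polynomial fitted to the nearest full window, so the
    band axis keeps its length (the networks' input reshape depends on it).
    """
    spectra = np.asarray(spectra, dtype=float)
    n_bands = spectra.shape[-1]
    if cfg.window > n_bands:
        raise ValueError(
            f"window {cfg.window} exceeds band count {n_bands}"
        )
    return savgol_filter(spectra, cfg.window, cfg.order, axis=-1, mode="interp")


def sg_coefficients(cfg: SgConfig) -> np.ndarray:
    """Convolution weights of the interior (central) SG filter.

    Useful for inspection: the weights always sum to 1, so constants pass
    through unchanged.
    """
    from scipy.signal import savgol_coeffs

    return savgol_coeffs(cfg.window, cfg.order)
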