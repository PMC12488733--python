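"""Successive projections algorithm (SPA) for wavelength selection.

SPA extracts a compact, minimally collinear subset of spectral bands in three
phases:

1. **Projection chains.**  Columns are standardized; starting from each
   candidate band, the remaining bands are repeatedly projected onto the
   orthogonal complement of the span of the bands already chosen, and the band
   with the largest residual norm is appended.  This greedily favours bands
   carrying information not already represented.
2. **PRESS evaluation.**  Every chain prefix (sizes ``k_min``..``k_max``) is
   scored by the prediction residual error sum of squares of an ordinary
   least-squares fit, measured on a validation set held out from calibration;
   the prefix with the globally lowest PRESS wins.
3. **Relevance pruning.**  Variables in the winning subset are ranked by a
   relevance index |b_j| * s_j (regression coefficient magnitude times column
   standard deviation); the final subset is the smallest top-ranked prefix
   whose PRESS is not significantly worse than the global minimum under a
   one-sided F-ratio test (default alpha = 0.25).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "SpaConfig",
    "SpaResult",
    "standardize",
    "projection_chain",
    "press_evaluate",
    "ftest_prune",
    "select_wavelengths",
]


@dataclass(frozen=True)
class SpaConfig:
    """SPA search window and statistical settings.

    ``k_min``/``k_max`` bound the candidate subset size (defaults 5 and the
    full band count); ``alpha`` is the F-test significance for phase-3
    pruning; ``validation_fraction`` is the share of the calibration data
    reserved for PRESS.  ``all_starts`` runs one projection chain per starting
    band; when False only the maximum-variance band seeds the chain.
    """

    k_min: int = 5
    k_max: int | None = None
    alpha: float = 0.25
    validation_fraction: float = 0.3
    all_starts: bool = True

    def __post_init__(self) -> None:
        if self.k_min < 1:
            raise ValueError("k_min must be >= 1")
        if self.k_max is not None and self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")


@dataclass
class SpaResult:
    """Selected band indices with the PRESS trace of the search."""

    selected: list[int]
    press_by_size: dict[int, float]
    relevance: dict[int, float] = field(default_factory=dict)
    press: float = float("nan")  # PRESS of the selected subset

    def wavelengths_nm(self, grid_values: np.ndarray) -> list[float]:
        return [float(grid_values[i]) for i in self.selected]

    def to_json(self, path: str | Path,
                grid_values: np.ndarray | None = None) -> None:
        payload = {
            "selected_indices": [int(i) for i in self.selected],
            "press_by_size": {str(k): v for k, v in
                              sorted(self.press_by_size.items())},
            "relevance": {str(k): v for k, v in self.relevance.items()},
            "press": self.press,
        }
        if grid_values is not None:
            payload["selected_nm"] = self.wavelengths_nm(grid_values)
        Path(path).write_text(json.dumps(payload, indent=2))


# --------------------------------------------------------------------------
# Phase 1: standardization and projection chains
# --------------------------------------------------------------------------

def standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise zero mean, unit variance (population convention)."""
    X = np.asarray(X, dtype=float)
    centers = X.mean(axis=0)
    scales = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(scales == 0)
    if zero.size:
        raise ValueError(f"zero-variance band(s) at column(s) {zero.tolist()}")
    return (X - centers) / scales, centers, scales


def projection_chain(Z: np.ndarray, start: int, k_max: int,
                     tol: float = 1e-10) -> list[int]:
    """Greedy orthogonal-projection chain of band indices.

    At each step every unselected column is projected onto the orthogonal
    complement of the span of the selected columns (maintained by Gram-Schmidt
    deflation) and the column with the largest residual norm is appended.
    The chain truncates early if the residual space is exhausted (e.g. exact
    collinearity).
    """
    Z = np.asarray(Z, dtype=float)
    n_bands = Z.shape[1]
    if not (0 <= start < n_bands):
        raise ValueError(f"start index {start} out of range")
    if k_max > n_bands:
        raise ValueError("k_max exceeds band count")

    residual = Z.copy()
    norm_floor = tol * max(np.linalg.norm(Z, axis=0).max(), 1.0)
    chain = [start]
    available = np.ones(n_bands, dtype=bool)
    available[start] = False

    current = start
    while len(chain) < k_max:
        col = residual[:, current]
        norm = np.linalg.norm(col)
        if norm <= norm_floor:
            logger.warning("projection chain truncated at length %d: "
                           "residual space exhausted", len(chain))
            break
        q = col / norm
        residual -= np.outer(q, q @ residual)  # deflate all columns at once
        norms = np.linalg.norm(residual, axis=0)
        norms[~available] = -1.0
        nxt = int(np.argmax(norms))
        if norms[nxt] <= norm_floor:
            logger.warning("projection chain truncated at length %d: "
                           "residual space exhausted", len(chain))
            break
        chain.append(nxt)
        available[nxt] = False
        current = nxt
    return chain


# --------------------------------------------------------------------------
# Phase 2: PRESS over chain prefixes
# --------------------------------------------------------------------------

def _ols_press(X_cal: np.ndarray, y_cal: np.ndarray, X_val: np.ndarray,
               y_val: np.ndarray, cols: list[int]) -> tuple[float, np.ndarray] | None:
    """OLS with intercept on ``cols``; returns (PRESS, coefficients).

    Returns None for rank-deficient designs.
    """
    design = np.column_stack([np.ones(X_cal.shape[0]), X_cal[:, cols]])
    beta, _, rank, _ = np.linalg.lstsq(design, y_cal, rcond=None)
    if rank < design.shape[1]:
        return None
    design_val = np.column_stack([np.ones(X_val.shape[0]), X_val[:, cols]])
    resid = y_val - design_val @ beta
    return float(resid @ resid), beta


def press_evaluate(chains: list[list[int]], X_cal: np.ndarray,
                   y_cal: np.ndarray, X_val: np.ndarray, y_val: np.ndarray,
                   cfg: SpaConfig) -> SpaResult:
    """Score every chain prefix by validation-set PRESS; keep the global best."""
    X_cal = np.asarray(X_cal, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_cal = np.asarray(y_cal, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    n_bands = X_cal.shape[1]
    k_max = cfg.k_max if cfg.k_max is not None else n_bands
    k_max = min(k_max, n_bands, X_cal.shape[0] - 2)

    press_by_size: dict[int, float] = {}
    best: tuple[float, list[int]] | None = None
    for chain in chains:
        for k in range(cfg.k_min, min(k_max, len(chain)) + 1):
            prefix = list(chain[:k])
            out = _ols_press(X_cal, y_cal, X_val, y_val, prefix)
            if out is None:
                logger.warning("rank-deficient prefix of size %d skipped", k)
                continue
            press, _ = out
            if k not in press_by_size or press < press_by_size[k]:
                press_by_size[k] = press
            if best is None or press < best[0]:
                best = (press, prefix)
    if best is None:
        raise ValueError("no valid chain prefix could be evaluated")
    return SpaResult(selected=best[1], press_by_size=press_by_size,
                     press=best[0])


# --------------------------------------------------------------------------
# Phase 3: relevance ranking and F-test pruning
# --------------------------------------------------------------------------

def ftest_prune(result: SpaResult, X_cal: np.ndarray, y_cal: np.ndarray,
                X_val: np.ndarray, y_val: np.ndarray,
                cfg: SpaConfig) -> SpaResult:
    """Shrink the winning subset to its significant core.

    Variables are ranked by relevance |b_j| * s_j; the smallest top-ranked
    prefix whose PRESS ratio to the global minimum stays below the one-sided
    F critical value F(alpha; n_val, n_val) is returned.
    """
    if not result.selected:
        raise ValueError("empty selection")
    n_val = np.asarray(y_val).size
    if n_val < 3:
        raise ValueError("need at least 3 validation samples for the F-test")

    cols = list(result.selected)
    out = _ols_press(X_cal, y_cal, X_val, y_val, cols)
    if out is None:
        raise ValueError("winning subset is rank-deficient on calibration data")
    press_full, beta = out
    sds = np.asarray(X_cal, dtype=float)[:, cols].std(axis=0, ddof=0)
    relevance = np.abs(beta[1:]) * sds  # skip intercept
    order = np.argsort(-relevance, kind="stable")
    ranked = [cols[i] for i in order]

    press_min = min(result.press, press_full)
    f_crit = stats.f.ppf(1.0 - cfg.alpha, n_val, n_val)

    chosen = ranked
    press_chosen = press_full
    for k in range(1, len(ranked) + 1):
        prefix = ranked[:k]
        out = _ols_press(X_cal, y_cal, X_val, y_val, prefix)
        if out is None:
            continue
        press_k, _ = out
        if press_k / press_min <= f_crit:
            chosen, press_chosen = prefix, press_k
            break

    return SpaResult(
        selected=chosen,
        press_by_size=result.press_by_size,
        relevance={int(c): float(r) for c, r in zip(cols, relevance)},
        press=press_chosen,
    )


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def select_wavelengths(X: np.ndarray, y: np.ndarray,
                       cfg: SpaConfig = SpaConfig(),
                       seed: int = 0) -> SpaResult:
    """Run all three SPA phases on a calibration set.

    ``X``/``y`` are the *training* partition only; a ``validation_fraction``
    share is split off internally (seeded) for PRESS, so the held-out test
    partition never leaks into selection.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_val = max(3, int(round(cfg.validation_fraction * n)))
    val_idx, cal_idx = perm[:n_val], perm[n_val:]
    X_cal, y_cal = X[cal_idx], y[cal_idx]
    X_val, y_val = X[val_idx], y[val_idx]

    Z, _, _ = standardize(X_cal)
    n_bands = X.shape[1]
    k_max = cfg.k_max if cfg.k_max is not None else n_bands
    k_max = min(k_max, n_bands, X_cal.shape[0] - 2)

    if cfg.all_starts:
        starts = range(n_bands)
    else:
        starts = [int(np.argmax(Z.std(axis=0)))]
    chains = [projection_chain(Z, s, k_max) for s in starts]

    result = press_evaluate(chains, X_cal, y_cal, X_val, y_val, cfg)
    return ftest_prune(result, X_cal, y_cal, X_val, y_val, cfg)
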