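"""Data partitioning and calibration metrics: R-squared, RMSE, RPD.

RPD (residual predictive deviation) is the standard deviation of the measured
values divided by the RMSE of prediction; in Vis-NIR calibration RPD > 2.0 is
read as good quantitative performance and RPD <= 1.4 as weak.  With the
population SD convention, RPD relates to R-squared as RPD = 1/sqrt(1 - R2),
which makes the two views of model quality mutually checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "PredictionSet",
    "MetricsReport",
    "SplitPlan",
    "r_squared",
    "rmse",
    "rpd",
    "rpd_band",
    "evaluate_predictions",
    "split_7_3",
    "degradation",
]


@dataclass(frozen=True)
class PredictionSet:
    """Measured and predicted analyte values for one evaluation split."""

    y: np.ndarray
    y_hat: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=float)
        y_hat = np.asarray(self.y_hat, dtype=float)
        if y.shape != y_hat.shape or y.ndim != 1:
            raise ValueError("y and y_hat must be 1-D arrays of equal length")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "y_hat", y_hat)

    @property
    def n(self) -> int:
        return self.y.size

    @property
    def y_bar(self) -> float:
        return float(self.y.mean())


@dataclass(frozen=True)
class MetricsReport:
    """R2 / RMSE / RPD with the qualitative RPD band for one split."""

    r2: float
    rmse: float
    sd: float
    rpd: float
    band: str
    sd_convention: str  # recorded because it shifts RPD by sqrt(n/(n-1))

    def as_dict(self) -> dict:
        return {
            "r2": self.r2, "rmse": self.rmse, "sd": self.sd,
            "rpd": self.rpd, "band": self.band,
            "sd_convention": self.sd_convention,
        }


def r_squared(p: PredictionSet) -> float:
    """Coefficient of determination: 1 - SSE/SST about the measured mean."""
    sst = float(np.sum((p.y - p.y_bar) ** 2))
    if sst == 0:
        raise ValueError("all measured values equal: R-squared undefined")
    sse = float(np.sum((p.y - p.y_hat) ** 2))
    return 1.0 - sse / sst


def rmse(p: PredictionSet) -> float:
    """Root mean squared prediction error, in analyte units."""
    if p.n < 1:
        raise ValueError("empty prediction set")
    return float(np.sqrt(np.mean((p.y - p.y_hat) ** 2)))


def _sd(y: np.ndarray, convention: str) -> float:
    if convention == "population":
        return float(np.std(y, ddof=0))
    if convention == "sample":
        return float(np.std(y, ddof=1))
    raise ValueError(f"unknown SD convention {convention!r}")


def rpd(p: PredictionSet, sd_convention: str = "sample") -> float:
    """Residual predictive deviation: SD of measured values / RMSE."""
    error = rmse(p)
    if error == 0:
        raise ValueError("RMSE is zero: prediction is perfect, RPD infinite")
    return _sd(p.y, sd_convention) / error


def rpd_band(value: float) -> str:
    """Qualitative reading of an RPD value."""
    if value > 2.0:
        return "good"
    if value > 1.4:
        return "intermediate"
    return "weak"


def evaluate_predictions(y: np.ndarray, y_hat: np.ndarray,
                         sd_convention: str = "sample") -> MetricsReport:
    """Full metric report for one split."""
    p = PredictionSet(y, y_hat)
    if p.n < 3:
        raise ValueError("need at least 3 samples for a metric report")
    r2 = r_squared(p)
    error = rmse(p)
    sd = _sd(p.y, sd_convention)
    ratio = sd / error if error > 0 else float("inf")
    return MetricsReport(r2=r2, rmse=error, sd=sd, rpd=ratio,
                         band=rpd_band(ratio), sd_convention=sd_convention)


# --------------------------------------------------------------------------
# Partitioning
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test index split."""

    train: np.ndarray
    test: np.ndarray
    ratio: float
    seed: int


def split_7_3(n_samples: int, seed: int, stratify_labels=None,
              train_fraction: float = 0.7) -> SplitPlan:
    """Seeded shuffle split with train size round(train_fraction * n).

    With ``stratify_labels`` (e.g. cultivar), the split is performed within
    each stratum so class ratios are preserved to within one sample.
    """
    if n_samples < 10:
        raise ValueError("need at least 10 samples to split")
    rng = np.random.default_rng(seed)

    if stratify_labels is None:
        perm = rng.permutation(n_samples)
        n_train = round(train_fraction * n_samples)
        train, test = perm[:n_train], perm[n_train:]
    else:
        labels = np.asarray(stratify_labels)
        if labels.size != n_samples:
            raise ValueError("stratify_labels length mismatch")
        train_parts, test_parts = [], []
        for value in np.unique(labels):
            idx = np.flatnonzero(labels == value)
            if idx.size < 2:
                raise ValueError(f"stratum {value!r} has fewer than 2 samples")
            idx = rng.permutation(idx)
            k = round(train_fraction * idx.size)
            k = min(max(k, 1), idx.size - 1)  # both sides non-empty per stratum
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train = np.concatenate(train_parts)
        test = np.concatenate(test_parts)

    return SplitPlan(train=np.sort(train), test=np.sort(test),
                     ratio=train_fraction, seed=seed)


# --------------------------------------------------------------------------
# External-validation degradation
# --------------------------------------------------------------------------

def degradation(metric_internal: float, metric_external: float) -> float:
    """Percent reduction from internal-test to external-validation metric.

    100 * (internal - external) / internal, rounded half-up to two decimals —
    the convention used when quoting cross-year performance loss.
    """
    if metric_internal <= 0:
        raise ValueError("internal metric must be positive")
    pct = 100.0 * (metric_internal - metric_external) / metric_internal
    return float(Decimal(repr(pct)).quantize(Decimal("0.01"),
                                             rounding=ROUND_HALF_UP))
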