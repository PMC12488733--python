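"""Model/Results surface for spectral analyte regression.

``SpectralRegression`` is constructed from data (spectra plus one analyte),
configured with a preprocessing choice (raw or Savitzky-Golay), a wavelength
selection choice (full spectrum or SPA), and one of the three network
architectures.  ``fit()`` runs the 7:3 internal split, executes the chosen
preprocessing/selection on the training partition only, trains the network,
and returns a ``SpectralRegressionResults`` carrying the fitted model,
per-split metrics, the SPA trace, and a ``summary()`` table.  External
datasets (e.g. a later harvest year) are scored with the frozen model via
``results.evaluate_external`` — never refitted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pomonet import models
from pomonet.evaluation import (MetricsReport, SplitPlan, degradation,
                                evaluate_predictions, split_7_3)
from pomonet.preprocessing import SgConfig, sg_smooth
from pomonet.spa import SpaConfig, SpaResult, select_wavelengths

__all__ = ["SpectralRegression", "SpectralRegressionResults"]


class SpectralRegression:
    """One analyte regressed on Vis-NIR spectra.

    Parameters
    ----------
    endog : (n,) measured analyte values, in analyte units.
    exog : (n, bands) reflectance spectra.
    wavelengths : optional band-center wavelengths in nm (for reporting).
    architecture : 'cnn' | 'cnn_bigru' | 'cnn_bigru_attention'.
    preprocessing : 'raw' | 'sg'.
    selection : 'full' | 'spa'.
    """

    def __init__(self, endog, exog, wavelengths=None,
                 architecture: str = "cnn_bigru_attention",
                 preprocessing: str = "raw", selection: str = "full",
                 sg_config: SgConfig = SgConfig(),
                 spa_config: SpaConfig = SpaConfig(),
                 stratify_labels=None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.size:
            raise ValueError("exog must be (n_samples, n_bands) matching endog")
        if preprocessing not in ("raw", "sg"):
            raise ValueError(f"unknown preprocessing {preprocessing!r}")
        if selection not in ("full", "spa"):
            raise ValueError(f"unknown selection {selection!r}")
        if architecture not in models.KINDS:
            raise ValueError(f"unknown architecture {architecture!r}")
        self.wavelengths = (np.asarray(wavelengths, dtype=float)
                            if wavelengths is not None else None)
        self.architecture = architecture
        self.preprocessing = preprocessing
        self.selection = selection
        self.sg_config = sg_config
        self.spa_config = spa_config
        self.stratify_labels = stratify_labels

    @classmethod
    def from_dataframe(cls, spectra: pd.DataFrame, analytes: pd.DataFrame,
                       analyte: str, **kwargs) -> "SpectralRegression":
        """Build from the CSV-shaped tables the pipeline reads and writes.

        ``spectra``: first column sample id, remaining columns labelled by
        wavelength; ``analytes``: per-sample analyte values.
        """
        wavelengths = np.array([float(c) for c in spectra.columns[1:]])
        X = spectra.iloc[:, 1:].to_numpy(float)
        y = analytes[analyte].to_numpy(float)
        labels = (analytes["cultivar"].to_numpy()
                  if "cultivar" in analytes else None)
        return cls(y, X, wavelengths=wavelengths, stratify_labels=labels,
                   **kwargs)

    def fit(self, train_config: models.TrainConfig | None = None,
            split_seed: int = 0, seed: int = 0) -> "SpectralRegressionResults":
        """Split 7:3, preprocess/select on the training side, train, score."""
        n = self.endog.size
        plan = split_7_3(n, split_seed, stratify_labels=self.stratify_labels)
        X = self.exog
        if self.preprocessing == "sg":
            X = sg_smooth(X, self.sg_config)

        X_train, y_train = X[plan.train], self.endog[plan.train]
        X_test, y_test = X[plan.test], self.endog[plan.test]

        spa_result: SpaResult | None = None
        selected = np.arange(X.shape[1])
        if self.selection == "spa":
            spa_result = select_wavelengths(X_train, y_train,
                                            cfg=self.spa_config, seed=seed)
            selected = np.array(sorted(spa_result.selected))
        X_train_sel = X_train[:, selected]
        X_test_sel = X_test[:, selected]

        cfg = train_config or models.TrainConfig.for_kind(
            self.architecture, seed=seed)
        spec = models.build(self.architecture, selected.size)
        trained = models.train(spec, cfg, X_train_sel, y_train)

        train_report = evaluate_predictions(
            y_train, models.predict(trained, X_train_sel))
        test_report = evaluate_predictions(
            y_test, models.predict(trained, X_test_sel))

        return SpectralRegressionResults(
            model=self, trained=trained, split=plan, selected_bands=selected,
            spa_result=spa_result, train_metrics=train_report,
            test_metrics=test_report)


@dataclass
class SpectralRegressionResults:
    """Fitted network with its split, selection trace, and metrics."""

    model: SpectralRegression
    trained: models.TrainedModel
    split: SplitPlan
    selected_bands: np.ndarray
    spa_result: SpaResult | None
    train_metrics: MetricsReport
    test_metrics: MetricsReport

    @property
    def n_selected(self) -> int:
        return int(self.selected_bands.size)

    @property
    def selected_nm(self) -> np.ndarray | None:
        if self.model.wavelengths is None:
            return None
        return self.model.wavelengths[self.selected_bands]

    def predict(self, exog) -> np.ndarray:
        """Predict analyte values for new spectra on the full band grid."""
        X = np.asarray(exog, dtype=float)
        if self.model.preprocessing == "sg":
            X = sg_smooth(X, self.model.sg_config)
        return models.predict(self.trained, X[:, self.selected_bands])

    def evaluate_external(self, exog, endog) -> MetricsReport:
        """Score an external set with the frozen model (no refit)."""
        return evaluate_predictions(np.asarray(endog, dtype=float).ravel(),
                                    self.predict(exog))

    def degradation_vs_external(self, external: MetricsReport) -> dict:
        """Percent reduction of test-set R2 and RPD on the external set.

        Entries are None when the internal metric is not positive (a percent
        reduction of a non-positive baseline carries no meaning).
        """
        return {
            "r2_pct": (degradation(self.test_metrics.r2, external.r2)
                       if self.test_metrics.r2 > 0 else None),
            "rpd_pct": (degradation(self.test_metrics.rpd, external.rpd)
                        if self.test_metrics.rpd > 0 else None),
        }

    def summary(self) -> str:
        m = self.model
        lines = [
            "Spectral analyte regression",
            "=" * 60,
            f"architecture:     {m.architecture}",
            f"preprocessing:    {m.preprocessing.upper()}",
            f"selection:        {m.selection}"
            + (f" ({self.n_selected} bands)" if m.selection == "spa" else ""),
            f"input bands:      {self.n_selected}",
            f"split:            {self.split.train.size} train / "
            f"{self.split.test.size} test (seed {self.split.seed})",
            f"parameters:       {self.trained.spec.param_count}",
            "-" * 60,
            f"{'split':<8}{'R2':>8}{'RMSE':>10}{'SD':>10}{'RPD':>8}  band",
        ]
        for name, rep in (("train", self.train_metrics),
                          ("test", self.test_metrics)):
            lines.append(
                f"{name:<8}{rep.r2:>8.3f}{rep.rmse:>10.4f}{rep.sd:>10.4f}"
                f"{rep.rpd:>8.3f}  {rep.band}")
        if self.selected_nm is not None and self.model.selection == "spa":
            nm = ", ".join(f"{w:.0f}" for w in self.selected_nm)
            lines.append("-" * 60)
            lines.append(f"selected wavelengths (nm): {nm}")
        lines.append("=" * 60)
        return "\n".join(lines)
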