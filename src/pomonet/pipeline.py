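"""End-to-end orchestration: ingest -> segment -> preprocess -> select ->
train -> evaluate, from a single declarative configuration.

A run produces a self-contained output directory: metrics (JSON and CSV),
the SPA trace when selection is active, a model checkpoint, the training
loss curve, and a provenance record (config, seeds, package version) so any
run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import pomonet
from pomonet import models
from pomonet.model_api import SpectralRegression
from pomonet.preprocessing import SgConfig
from pomonet.spa import SpaConfig
from pomonet.synthetic import OpticalModel, SpectralDataset, generate_dataset

__all__ = ["RunConfig", "run"]

ANALYTES = ("vc", "ssc", "sp")


@dataclass
class RunConfig:
    """One pipeline run: data source, input configuration, model, analyte.

    The four input configurations RAW / SG / SPA+RAW / SPA+SG correspond to
    ``preprocessing`` in {raw, sg} crossed with ``selection`` in {full, spa}.
    """

    analyte: str = "sp"
    preprocessing: str = "raw"          # raw | sg
    selection: str = "full"             # full | spa
    architecture: str = "cnn_bigru_attention"
    # data: either CSV paths or a synthetic spec
    spectra_csv: str | None = None
    analytes_csv: str | None = None
    synthetic_n: int | None = None
    synthetic_seed: int = 0
    # external validation set (optional)
    external_spectra_csv: str | None = None
    external_analytes_csv: str | None = None
    external_synthetic_n: int | None = None
    external_synthetic_seed: int | None = None
    # schedules and seeds
    split_seed: int = 0
    seed: int = 0
    epochs: int | None = None
    sg_window: int = 11
    sg_order: int = 2
    spa_k_min: int = 5
    spa_k_max: int | None = None
    spa_alpha: float = 0.25
    out_dir: str = "run_output"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _load_dataset(cfg: RunConfig) -> SpectralDataset:
    if cfg.spectra_csv and cfg.analytes_csv:
        return SpectralDataset.from_csv(cfg.spectra_csv, cfg.analytes_csv)
    if cfg.synthetic_n:
        return generate_dataset(cfg.synthetic_n, seed=cfg.synthetic_seed)
    raise ValueError("config must name CSV inputs or a synthetic sample count")


def _load_external(cfg: RunConfig) -> SpectralDataset | None:
    if cfg.external_spectra_csv and cfg.external_analytes_csv:
        return SpectralDataset.from_csv(cfg.external_spectra_csv,
                                        cfg.external_analytes_csv)
    if cfg.external_synthetic_n:
        seed = (cfg.external_synthetic_seed
                if cfg.external_synthetic_seed is not None
                else cfg.synthetic_seed + 1)
        return generate_dataset(cfg.external_synthetic_n, seed=seed)
    return None


def run(cfg: RunConfig) -> dict:
    """Execute one configured run; returns the report bundle as a dict."""
    if cfg.analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {cfg.analyte!r}")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    dataset = _load_dataset(cfg)
    timings["ingest_s"] = time.perf_counter() - t0

    regression = SpectralRegression(
        dataset.analyte(cfg.analyte), dataset.X,
        wavelengths=dataset.grid.values,
        architecture=cfg.architecture,
        preprocessing=cfg.preprocessing,
        selection=cfg.selection,
        sg_config=SgConfig(cfg.sg_window, cfg.sg_order),
        spa_config=SpaConfig(k_min=cfg.spa_k_min, k_max=cfg.spa_k_max,
                             alpha=cfg.spa_alpha),
    )
    train_config = models.TrainConfig.for_kind(cfg.architecture, seed=cfg.seed)
    if cfg.epochs is not None:
        decay = (min(train_config.lr_decay_epoch, max(cfg.epochs * 7 // 10, 1))
                 if train_config.lr_decay_epoch is not None else None)
        train_config = models.TrainConfig.for_kind(
            cfg.architecture, seed=cfg.seed, epochs=cfg.epochs,
            lr_decay_epoch=decay)

    t0 = time.perf_counter()
    results = regression.fit(train_config=train_config,
                             split_seed=cfg.split_seed, seed=cfg.seed)
    timings["fit_s"] = time.perf_counter() - t0

    report = {
        "analyte": cfg.analyte,
        "input_config": (f"{'SPA+' if cfg.selection == 'spa' else ''}"
                         f"{cfg.preprocessing.upper()}"),
        "architecture": cfg.architecture,
        "n_selected_bands": results.n_selected,
        "train": results.train_metrics.as_dict(),
        "test": results.test_metrics.as_dict(),
    }

    external = _load_external(cfg)
    if external is not None:
        t0 = time.perf_counter()
        ext_report = results.evaluate_external(
            external.X, external.analyte(cfg.analyte))
        timings["external_s"] = time.perf_counter() - t0
        report["external"] = ext_report.as_dict()
        report["degradation"] = results.degradation_vs_external(ext_report)

    # ---- artifacts -------------------------------------------------------
    (out / "metrics.json").write_text(json.dumps(report, indent=2))
    rows = [{"analyte": cfg.analyte, "input_config": report["input_config"],
             "model": cfg.architecture, "split": split, **metrics}
            for split, metrics in (("train", report["train"]),
                                   ("test", report["test"]),
                                   *((("external", report["external"]),)
                                     if "external" in report else ()))]
    pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)

    if results.spa_result is not None:
        results.spa_result.to_json(out / "spa.json",
                                   grid_values=dataset.grid.values)
    models.save_model(results.trained, out / "model.zip")
    pd.DataFrame({
        "epoch": np.arange(len(results.trained.loss_curve)),
        "lr": results.trained.lr_curve,
        "loss": results.trained.loss_curve,
    }).to_csv(out / "loss_curve.csv", index=False)

    provenance = {
        "config": asdict(cfg),
        "package_version": pomonet.__version__,
        "numpy_version": np.__version__,
        "timings": timings,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    report["out_dir"] = str(out)
    return report
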