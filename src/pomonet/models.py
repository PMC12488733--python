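"""The three spectral regression architectures and their training loop.

Each model consumes a spectrum reshaped to an [n x 1 x 1] pseudo-image
(n = number of input bands, full spectrum or an SPA subset) and regresses one
analyte at a time:

* **cnn** — two conv blocks (8 then 32 filters, 3x1 kernels, each with batch
  norm, ReLU and 2x1 max pooling), dropout 0.4, dense 32, dense 1.
* **cnn_bigru** — a conv branch (16 filters, 3x1 kernel, batch norm, ReLU,
  3x1 max pooling, flatten, dense 25) in parallel with a bidirectional GRU
  branch (two 35-unit GRU layers, one reading the band sequence and one its
  reversal); final hidden states (70 features) are concatenated with the conv
  features (25) and fed to the regression layer.
* **cnn_bigru_attention** — the same, with single-head dot-product
  self-attention (key/query dimension 50) inserted after the concatenation.

Training uses Adam with mean-squared-error loss, coupled L2 regularization,
and a step learning-rate schedule; all randomness flows from one seed, so a
fixed seed gives bit-reproducible weights.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from pomonet import nn
from pomonet.autograd import Tensor, concat

__all__ = [
    "ModelSpec", "TrainConfig", "TrainedModel",
    "build", "train", "predict", "learning_rate",
    "save_model", "load_model", "KINDS",
]

KINDS = ("cnn", "cnn_bigru", "cnn_bigru_attention")

_CONV_KERNEL = 3
_CNN_FILTERS = (8, 32)
_CNN_DENSE = 32
_BRANCH_FILTERS = 16
_BRANCH_POOL = 3
_BRANCH_DENSE = 25
_GRU_HIDDEN = 35
_ATTN_DIM = 50
_DROPOUT = 0.4

#: Smallest band count whose axis survives the cnn's two 2x1 pooling stages.
MIN_BANDS_CNN = 4
#: The hybrid conv branch pools once with a 3x1 window.
MIN_BANDS_HYBRID = 3


# --------------------------------------------------------------------------
# Specs and configs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """A fully dimensioned layer plan for one architecture and band count."""

    kind: str
    n_bands: int
    layers: tuple[dict, ...]
    param_count: int


@dataclass(frozen=True)
class TrainConfig:
    """Adam optimization schedule.

    The plain cnn trains 500 epochs at learning rate 1e-3; the hybrids
    train 1000 epochs from 1e-2 with a single x0.1 decay at
    ``lr_decay_epoch`` (default 700, within the 600-800 window).  All three
    use L2 factor 0.01 — at a few hundred training samples the hybrids'
    ~13k parameters overfit under weaker decay.
    """

    epochs: int = 500
    initial_lr: float = 0.001
    l2_factor: float = 0.01
    lr_decay_factor: float | None = None
    lr_decay_epoch: int | None = None
    batch_size: int = 16
    seed: int = 0
    standardize_inputs: bool = True

    @classmethod
    def for_kind(cls, kind: str, seed: int = 0, **overrides) -> "TrainConfig":
        if kind == "cnn":
            cfg = cls(epochs=500, initial_lr=0.001, l2_factor=0.01, seed=seed)
        elif kind in ("cnn_bigru", "cnn_bigru_attention"):
            cfg = cls(epochs=1000, initial_lr=0.01, l2_factor=0.01,
                      lr_decay_factor=0.1, lr_decay_epoch=700, seed=seed)
        else:
            raise ValueError(f"unknown model kind {kind!r}")
        return replace(cfg, **overrides) if overrides else cfg

    def __post_init__(self) -> None:
        if self.lr_decay_epoch is not None and not (
                0 < self.lr_decay_epoch <= self.epochs):
            raise ValueError("lr_decay_epoch must lie inside the epoch range")


def learning_rate(cfg: TrainConfig, epoch: int) -> float:
    """Learning rate in force at ``epoch`` (0-based)."""
    if cfg.lr_decay_epoch is not None and epoch >= cfg.lr_decay_epoch:
        return cfg.initial_lr * cfg.lr_decay_factor
    return cfg.initial_lr


# --------------------------------------------------------------------------
# Layer-plan construction and parameter arithmetic
# --------------------------------------------------------------------------

def _conv_params(c_in: int, c_out: int, kernel: int = _CONV_KERNEL) -> int:
    return kernel * c_in * c_out + c_out


def _dense_params(n_in: int, n_out: int) -> int:
    return n_in * n_out + n_out


def _bn_params(channels: int) -> int:
    return 2 * channels


def _gru_params(n_in: int, hidden: int) -> int:
    return 3 * (n_in * hidden + hidden * hidden + hidden)


def build(spec_kind: str, n_bands: int) -> ModelSpec:
    """Dimension the layer plan for ``spec_kind`` at ``n_bands`` inputs."""
    if spec_kind not in KINDS:
        raise ValueError(f"unknown model kind {spec_kind!r}")

    if spec_kind == "cnn":
        if n_bands < MIN_BANDS_CNN:
            raise ValueError(
                f"cnn needs at least {MIN_BANDS_CNN} bands "
                f"(two 2x1 pooling stages), got {n_bands}")
        len1 = n_bands // 2
        len2 = len1 // 2
        flat = _CNN_FILTERS[1] * len2
        layers = (
            {"layer": "conv", "filters": _CNN_FILTERS[0], "kernel": [3, 1],
             "out_length": n_bands, "params": _conv_params(1, _CNN_FILTERS[0])},
            {"layer": "batchnorm", "channels": _CNN_FILTERS[0],
             "params": _bn_params(_CNN_FILTERS[0])},
            {"layer": "relu", "params": 0},
            {"layer": "maxpool", "window": [2, 1], "out_length": len1,
             "params": 0},
            {"layer": "conv", "filters": _CNN_FILTERS[1], "kernel": [3, 1],
             "out_length": len1,
             "params": _conv_params(_CNN_FILTERS[0], _CNN_FILTERS[1])},
            {"layer": "batchnorm", "channels": _CNN_FILTERS[1],
             "params": _bn_params(_CNN_FILTERS[1])},
            {"layer": "relu", "params": 0},
            {"layer": "maxpool", "window": [2, 1], "out_length": len2,
             "params": 0},
            {"layer": "dropout", "rate": _DROPOUT, "params": 0},
            {"layer": "flatten", "width": flat, "params": 0},
            {"layer": "dense", "units": _CNN_DENSE,
             "params": _dense_params(flat, _CNN_DENSE)},
            {"layer": "dense", "units": 1, "params": _dense_params(_CNN_DENSE, 1)},
        )
        return ModelSpec(spec_kind, n_bands, layers,
                         sum(l["params"] for l in layers))

    if n_bands < MIN_BANDS_HYBRID:
        raise ValueError(
            f"{spec_kind} needs at least {MIN_BANDS_HYBRID} bands "
            f"(one 3x1 pooling stage), got {n_bands}")
    pooled = n_bands // _BRANCH_POOL
    flat = _BRANCH_FILTERS * pooled
    merged = _BRANCH_DENSE + 2 * _GRU_HIDDEN  # 25 + 70 = 95
    layers = [
        {"layer": "conv", "branch": "cnn", "filters": _BRANCH_FILTERS,
         "kernel": [3, 1], "out_length": n_bands,
         "params": _conv_params(1, _BRANCH_FILTERS)},
        {"layer": "batchnorm", "branch": "cnn", "channels": _BRANCH_FILTERS,
         "params": _bn_params(_BRANCH_FILTERS)},
        {"layer": "relu", "branch": "cnn", "params": 0},
        {"layer": "maxpool", "branch": "cnn", "window": [3, 1],
         "out_length": pooled, "params": 0},
        {"layer": "flatten", "branch": "cnn", "width": flat, "params": 0},
        {"layer": "dense", "branch": "cnn", "units": _BRANCH_DENSE,
         "params": _dense_params(flat, _BRANCH_DENSE)},
        {"layer": "gru", "branch": "bigru", "direction": "forward",
         "hidden": _GRU_HIDDEN, "params": _gru_params(1, _GRU_HIDDEN)},
        {"layer": "gru", "branch": "bigru", "direction": "reverse",
         "hidden": _GRU_HIDDEN, "params": _gru_params(1, _GRU_HIDDEN)},
        {"layer": "concat", "width": merged, "params": 0},
    ]
    if spec_kind == "cnn_bigru_attention":
        attn_params = 2 * _dense_params(1, _ATTN_DIM) + _dense_params(1, _ATTN_DIM)
        layers.append({"layer": "self_attention", "d_k": _ATTN_DIM,
                       "d_v": _ATTN_DIM, "params": attn_params})
        layers.append({"layer": "dense", "units": 1,
                       "params": _dense_params(_ATTN_DIM, 1)})
    else:
        layers.append({"layer": "dense", "units": 1,
                       "params": _dense_params(merged, 1)})
    layers = tuple(layers)
    return ModelSpec(spec_kind, n_bands, layers,
                     sum(l["params"] for l in layers))


# --------------------------------------------------------------------------
# Networks
# --------------------------------------------------------------------------

class _CnnNet(nn.Module):
    def __init__(self, n_bands: int, rng: np.random.Generator):
        len2 = (n_bands // 2) // 2
        self.conv1 = nn.Conv1d(1, _CNN_FILTERS[0], _CONV_KERNEL, rng)
        self.bn1 = nn.BatchNorm1d(_CNN_FILTERS[0])
        self.pool1 = nn.MaxPool1d(2)
        self.conv2 = nn.Conv1d(_CNN_FILTERS[0], _CNN_FILTERS[1], _CONV_KERNEL, rng)
        self.bn2 = nn.BatchNorm1d(_CNN_FILTERS[1])
        self.pool2 = nn.MaxPool1d(2)
        self.dropout = nn.Dropout(_DROPOUT, rng)
        self.fc1 = nn.Dense(_CNN_FILTERS[1] * len2, _CNN_DENSE, rng)
        self.fc2 = nn.Dense(_CNN_DENSE, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        batch = x.data.shape[0]
        h = x.reshape(batch, 1, -1)
        h = self.pool1(self.bn1(self.conv1(h)).relu())
        h = self.pool2(self.bn2(self.conv2(h)).relu())
        h = self.dropout(h).reshape(batch, -1)
        return self.fc2(self.fc1(h))


class _HybridNet(nn.Module):
    def __init__(self, n_bands: int, rng: np.random.Generator,
                 attention: bool):
        pooled = n_bands // _BRANCH_POOL
        self.conv = nn.Conv1d(1, _BRANCH_FILTERS, _CONV_KERNEL, rng)
        self.bn = nn.BatchNorm1d(_BRANCH_FILTERS)
        self.pool = nn.MaxPool1d(_BRANCH_POOL)
        self.fc_branch = nn.Dense(_BRANCH_FILTERS * pooled, _BRANCH_DENSE, rng)
        self.gru_fwd = nn.GRU(1, _GRU_HIDDEN, rng, reverse=False)
        self.gru_bwd = nn.GRU(1, _GRU_HIDDEN, rng, reverse=True)
        merged = _BRANCH_DENSE + 2 * _GRU_HIDDEN
        if attention:
            self.attention = nn.SelfAttention(_ATTN_DIM, _ATTN_DIM, rng)
            self.head = nn.Dense(_ATTN_DIM, 1, rng)
        else:
            self.attention = None
            self.head = nn.Dense(merged, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        batch = x.data.shape[0]
        img = x.reshape(batch, 1, -1)
        cnn = self.pool(self.bn(self.conv(img)).relu()).reshape(batch, -1)
        cnn = self.fc_branch(cnn)
        seq = x.reshape(batch, -1, 1)
        features = concat([cnn, self.gru_fwd(seq), self.gru_bwd(seq)], axis=1)
        if self.attention is not None:
            features = self.attention(features)
        return self.head(features)


def _make_net(spec: ModelSpec, rng: np.random.Generator) -> nn.Module:
    if spec.kind == "cnn":
        return _CnnNet(spec.n_bands, rng)
    return _HybridNet(spec.n_bands, rng,
                      attention=spec.kind == "cnn_bigru_attention")


# --------------------------------------------------------------------------
# Training
# --------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """Frozen network with its input/output scaling and training history."""

    spec: ModelSpec
    net: nn.Module
    x_center: np.ndarray
    x_scale: np.ndarray
    y_center: float
    y_scale: float
    loss_curve: list[float] = field(default_factory=list)
    lr_curve: list[float] = field(default_factory=list)
    cfg: TrainConfig | None = None


def train(spec: ModelSpec, cfg: TrainConfig, X_train: np.ndarray,
          y_train: np.ndarray) -> TrainedModel:
    """Fit one analyte with Adam + MSE under ``cfg``.

    Inputs are standardized per band and the target standardized to zero
    mean/unit SD (statistics fitted on the training data only and frozen into
    the returned model); predictions are mapped back to analyte units.
    """
    X = np.asarray(X_train, dtype=float)
    y = np.asarray(y_train, dtype=float).ravel()
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in training data")
    if X.shape[1] != spec.n_bands:
        raise ValueError(f"expected {spec.n_bands} bands, got {X.shape[1]}")
    if X.shape[0] != y.size:
        raise ValueError("X and y sample counts differ")

    rng = np.random.default_rng(cfg.seed)
    net = _make_net(spec, rng)
    if net.n_parameters() != spec.param_count:
        raise AssertionError("network parameters disagree with the layer plan")

    if cfg.standardize_inputs:
        x_center = X.mean(axis=0)
        x_scale = X.std(axis=0, ddof=0)
        x_scale[x_scale == 0] = 1.0
    else:
        x_center = np.zeros(X.shape[1])
        x_scale = np.ones(X.shape[1])
    Xs = (X - x_center) / x_scale
    y_center = float(y.mean())
    y_scale = float(y.std(ddof=0)) or 1.0
    ys = (y - y_center) / y_scale

    optimizer = nn.Adam(net.parameters(), l2_factor=cfg.l2_factor)
    model = TrainedModel(spec, net, x_center, x_scale, y_center, y_scale,
                         cfg=cfg)
    n = X.shape[0]
    net.set_training(True)
    for epoch in range(cfg.epochs):
        lr = learning_rate(cfg, epoch)
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Tensor(Xs[idx])
            yb = Tensor(ys[idx].reshape(-1, 1))
            pred = net(xb)
            diff = pred - yb
            loss = (diff * diff).mean()
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step(lr)
            epoch_loss += float(loss.data) * idx.size
        model.loss_curve.append(epoch_loss / n)
        model.lr_curve.append(lr)
    net.set_training(False)
    return model


def predict(model: TrainedModel, X: np.ndarray,
            batch_size: int = 256) -> np.ndarray:
    """Deterministic predictions in analyte units, one value per sample."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.spec.n_bands:
        raise ValueError(
            f"model expects {model.spec.n_bands} bands, got {X.shape[1]}")
    model.net.set_training(False)
    Xs = (X - model.x_center) / model.x_scale
    outputs = []
    for start in range(0, Xs.shape[0], batch_size):
        out = model.net(Tensor(Xs[start:start + batch_size]))
        outputs.append(out.data.ravel())
    scaled = np.concatenate(outputs)
    return model.y_center + model.y_scale * scaled


# --------------------------------------------------------------------------
# Checkpoints: plan JSON + weight blobs in one zip archive
# --------------------------------------------------------------------------

def _named_parameters(net: nn.Module, prefix: str = "") -> list[tuple[str, nn.Parameter]]:
    named = []
    for attr, value in vars(net).items():
        if isinstance(value, nn.Parameter):
            named.append((f"{prefix}{attr}", value))
        elif isinstance(value, nn.Module):
            named.extend(_named_parameters(value, f"{prefix}{attr}."))
    return named


def save_model(model: TrainedModel, path: str | Path) -> None:
    path = Path(path)
    plan = {
        "kind": model.spec.kind,
        "n_bands": model.spec.n_bands,
        "param_count": model.spec.param_count,
        "layers": list(model.spec.layers),
        "x_center": model.x_center.tolist(),
        "x_scale": model.x_scale.tolist(),
        "y_center": model.y_center,
        "y_scale": model.y_scale,
        "loss_curve": model.loss_curve,
        "lr_curve": model.lr_curve,
    }
    with zipfile.ZipFile(path, "w") as archive:
        archive.writestr("plan.json", json.dumps(plan))
        for name, param in _named_parameters(model.net):
            archive.writestr(f"weights/{name}.npy", param.data.tobytes())
            archive.writestr(f"weights/{name}.shape.json",
                             json.dumps(list(param.data.shape)))
        for attr, value in _named_buffers(model.net):
            archive.writestr(f"buffers/{attr}.npy", value.tobytes())
            archive.writestr(f"buffers/{attr}.shape.json",
                             json.dumps(list(value.shape)))


def _named_buffers(net: nn.Module, prefix: str = "") -> list[tuple[str, np.ndarray]]:
    named = []
    for attr, value in vars(net).items():
        if isinstance(value, nn.BatchNorm1d):
            named.append((f"{prefix}{attr}.running_mean", value.running_mean))
            named.append((f"{prefix}{attr}.running_var", value.running_var))
        elif isinstance(value, nn.Module):
            named.extend(_named_buffers(value, f"{prefix}{attr}."))
    return named


def load_model(path: str | Path) -> TrainedModel:
    path = Path(path)
    with zipfile.ZipFile(path) as archive:
        plan = json.loads(archive.read("plan.json"))
        spec = build(plan["kind"], plan["n_bands"])
        net = _make_net(spec, np.random.default_rng(0))
        for name, param in _named_parameters(net):
            shape = json.loads(archive.read(f"weights/{name}.shape.json"))
            param.data = np.frombuffer(
                archive.read(f"weights/{name}.npy"), dtype=float
            ).reshape(shape).copy()
        for attr, value in _named_buffers(net):
            shape = json.loads(archive.read(f"buffers/{attr}.shape.json"))
            value[:] = np.frombuffer(
                archive.read(f"buffers/{attr}.npy"), dtype=float
            ).reshape(shape)
    net.set_training(False)
    model = TrainedModel(
        spec, net,
        np.array(plan["x_center"]), np.array(plan["x_scale"]),
        plan["y_center"], plan["y_scale"],
        loss_curve=plan["loss_curve"], lr_curve=plan["lr_curve"],
    )
    return model
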