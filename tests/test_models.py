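"""Architecture plans, parameter arithmetic, training loop, checkpoints."""

import numpy as np
import pytest

from pomonet import models
from pomonet.models import (ModelSpec, TrainConfig, build, learning_rate,
                            load_model, predict, save_model, train)


def cnn_param_formula(n):
    len2 = (n // 2) // 2
    return ((3 * 1 * 8 + 8) + 2 * 8 + (3 * 8 * 32 + 32) + 2 * 32
            + (32 * len2 * 32 + 32) + (32 * 1 + 1))


def hybrid_param_formula(n, attention):
    pooled = n // 3
    gru = 3 * (1 * 35 + 35 * 35 + 35)
    total = ((3 * 1 * 16 + 16) + 2 * 16 + (16 * pooled * 25 + 25) + 2 * gru)
    if attention:
        total += 3 * (1 * 50 + 50) + (50 * 1 + 1)
    else:
        total += 95 * 1 + 1
    return total


class TestBuild:
    @pytest.mark.parametrize("n_bands", [4, 5, 11, 20, 360])
    def test_cnn_param_count(self, n_bands):
        spec = build("cnn", n_bands)
        assert spec.param_count == cnn_param_formula(n_bands)

    @pytest.mark.parametrize("kind,attention", [
        ("cnn_bigru", False), ("cnn_bigru_attention", True)])
    @pytest.mark.parametrize("n_bands", [3, 5, 20, 360])
    def test_hybrid_param_count(self, kind, attention, n_bands):
        spec = build(kind, n_bands)
        assert spec.param_count == hybrid_param_formula(n_bands, attention)

    def test_merge_width_95(self):
        for kind in ("cnn_bigru", "cnn_bigru_attention"):
            spec = build(kind, 10)
            concat = [l for l in spec.layers if l["layer"] == "concat"][0]
            assert concat["width"] == 95  # 25 conv + 2x35 GRU

    def test_layer_params_sum_to_total(self):
        for kind in models.KINDS:
            spec = build(kind, 12)
            assert sum(l["params"] for l in spec.layers) == spec.param_count

    def test_minimum_bands_enforced(self):
        with pytest.raises(ValueError, match="at least 4"):
            build("cnn", 3)
        with pytest.raises(ValueError, match="at least 3"):
            build("cnn_bigru", 2)
        with pytest.raises(ValueError, match="unknown"):
            build("mlp", 10)

    def test_network_matches_plan(self, rng):
        for kind in models.KINDS:
            spec = build(kind, 9)
            net = models._make_net(spec, rng)
            assert net.n_parameters() == spec.param_count


class TestTrainConfig:
    def test_cnn_defaults(self):
        cfg = TrainConfig.for_kind("cnn")
        assert (cfg.epochs, cfg.initial_lr, cfg.l2_factor) == (500, 1e-3, 0.01)
        assert cfg.lr_decay_epoch is None

    def test_hybrid_defaults(self):
        for kind in ("cnn_bigru", "cnn_bigru_attention"):
            cfg = TrainConfig.for_kind(kind)
            assert (cfg.epochs, cfg.initial_lr) == (1000, 1e-2)
            assert cfg.lr_decay_factor == 0.1
            assert 600 <= cfg.lr_decay_epoch <= 800

    def test_schedule_single_drop(self):
        cfg = TrainConfig.for_kind("cnn_bigru")
        lrs = [learning_rate(cfg, e) for e in range(cfg.epochs)]
        drops = [e for e in range(1, cfg.epochs) if lrs[e] < lrs[e - 1]]
        assert len(drops) == 1
        assert 600 <= drops[0] <= 800
        assert lrs[drops[0]] == pytest.approx(0.1 * cfg.initial_lr)

    def test_decay_epoch_bounds_checked(self):
        with pytest.raises(ValueError, match="epoch range"):
            TrainConfig(epochs=100, lr_decay_factor=0.1, lr_decay_epoch=200)


def _affine_problem(rng, n=80, bands=8):
    X = rng.random((n, bands))
    y = 2.0 + X @ np.linspace(-1, 1, bands)
    return X, y


class TestTraining:
    def test_cnn_learns_affine_target(self, rng):
        X, y = _affine_problem(rng)
        spec = build("cnn", 8)
        cfg = TrainConfig.for_kind("cnn", epochs=200)
        model = train(spec, cfg, X, y)
        pred = predict(model, X)
        resid = y - pred
        assert 1 - resid.var() / y.var() > 0.9
        assert len(model.loss_curve) == 200
        assert model.loss_curve[-1] < model.loss_curve[0]

    def test_training_reproducible_from_seed(self, rng):
        X, y = _affine_problem(rng, n=40)
        spec = build("cnn_bigru", 8)
        cfg = TrainConfig.for_kind("cnn_bigru", epochs=5, lr_decay_epoch=4)
        a = train(spec, cfg, X, y)
        b = train(spec, cfg, X, y)
        np.testing.assert_array_equal(predict(a, X), predict(b, X))

    def test_prediction_deterministic_after_training(self, rng):
        X, y = _affine_problem(rng, n=40)
        spec = build("cnn", 8)
        model = train(spec, TrainConfig.for_kind("cnn", epochs=5), X, y)
        np.testing.assert_array_equal(predict(model, X), predict(model, X))

    def test_band_count_mismatch_rejected(self, rng):
        X, y = _affine_problem(rng, n=40)
        spec = build("cnn", 8)
        model = train(spec, TrainConfig.for_kind("cnn", epochs=2), X, y)
        with pytest.raises(ValueError, match="bands"):
            predict(model, X[:, :5])
        with pytest.raises(ValueError, match="bands"):
            train(spec, TrainConfig.for_kind("cnn", epochs=2), X[:, :5], y)

    def test_non_finite_training_data_rejected(self, rng):
        X, y = _affine_problem(rng, n=40)
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train(build("cnn", 8), TrainConfig.for_kind("cnn", epochs=1), X, y)

    def test_predictions_in_analyte_units(self, rng):
        X, y = _affine_problem(rng, n=60)
        y = y * 100 + 500  # far from standardized range
        spec = build("cnn", 8)
        model = train(spec, TrainConfig.for_kind("cnn", epochs=100), X, y)
        pred = predict(model, X)
        assert abs(pred.mean() - y.mean()) < 0.1 * y.std()


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, rng):
        X, y = _affine_problem(rng, n=40)
        for kind in models.KINDS:
            spec = build(kind, 8)
            cfg = TrainConfig.for_kind(kind, epochs=3, **(
                {"lr_decay_epoch": 2} if kind != "cnn" else {}))
            model = train(spec, cfg, X, y)
            path = tmp_path / f"{kind}.zip"
            save_model(model, path)
            back = load_model(path)
            np.testing.assert_array_equal(predict(model, X),
                                          predict(back, X))
            assert back.spec.param_count == spec.param_count
            assert back.loss_curve == model.loss_curve
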