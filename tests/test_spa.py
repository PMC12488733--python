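"""SPA phases: standardization, projection chains, PRESS, F-test pruning."""

import numpy as np
import pytest

from pomonet.spa import (SpaConfig, _ols_press, ftest_prune, press_evaluate,
                         projection_chain, select_wavelengths, standardize)


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SpaConfig(k_min=0)
        with pytest.raises(ValueError):
            SpaConfig(k_min=5, k_max=4)
        with pytest.raises(ValueError):
            SpaConfig(alpha=1.5)
        with pytest.raises(ValueError):
            SpaConfig(validation_fraction=0.0)


class TestStandardize:
    def test_zero_mean_unit_variance(self, rng):
        X = rng.normal(3.0, 2.0, size=(50, 6))
        Z, centers, scales = standardize(X)
        np.testing.assert_allclose(Z.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(Z.std(axis=0, ddof=0), 1, atol=1e-12)
        np.testing.assert_allclose(centers, X.mean(axis=0))

    def test_zero_variance_band_named(self):
        X = np.ones((10, 3))
        X[:, 0] = np.arange(10)
        with pytest.raises(ValueError, match=r"\[1, 2\]"):
            standardize(X)


class TestProjectionChain:
    def test_no_duplicates_and_full_length(self, rng):
        Z, _, _ = standardize(rng.normal(size=(40, 8)))
        chain = projection_chain(Z, start=2, k_max=8)
        assert chain[0] == 2
        assert len(chain) == 8
        assert len(set(chain)) == 8

    def test_duplicate_columns_never_both_selected(self, rng):
        X = rng.normal(size=(40, 5))
        X = np.column_stack([X, X[:, 0]])  # column 5 duplicates column 0
        Z, _, _ = standardize(X)
        for start in range(6):
            chain = projection_chain(Z, start, k_max=6)
            assert not ({0, 5} <= set(chain)), (
                "exact duplicates must exhaust the residual space")

    def test_chain_prefers_orthogonal_information(self, rng):
        # Columns 0 and 1 nearly collinear; column 2 independent: after
        # starting at 0, the chain must pick 2 before 1.
        base = rng.normal(size=50)
        X = np.column_stack([base, base + 1e-3 * rng.normal(size=50),
                             rng.normal(size=50)])
        Z, _, _ = standardize(X)
        chain = projection_chain(Z, 0, k_max=3)
        assert chain[1] == 2

    def test_start_bounds_checked(self, rng):
        Z, _, _ = standardize(rng.normal(size=(20, 4)))
        with pytest.raises(ValueError, match="out of range"):
            projection_chain(Z, 4, 4)
        with pytest.raises(ValueError, match="exceeds band count"):
            projection_chain(Z, 0, 5)


def _brute_force_prefix_press(chains, X_cal, y_cal, X_val, y_val, cfg):
    """Independent re-enumeration of every scored candidate subset."""
    best = None
    k_max = min(cfg.k_max or X_cal.shape[1], X_cal.shape[1],
                X_cal.shape[0] - 2)
    for chain in chains:
        for k in range(cfg.k_min, min(k_max, len(chain)) + 1):
            out = _ols_press(X_cal, y_cal, X_val, y_val, list(chain[:k]))
            if out is None:
                continue
            if best is None or out[0] < best:
                best = out[0]
    return best


class TestPressEvaluate:
    def test_winner_matches_brute_force_over_candidates(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n_bands = int(rng.integers(3, 7))
            X = rng.normal(size=(40, n_bands))
            beta = rng.normal(size=n_bands)
            y = X @ beta + 0.3 * rng.normal(size=40)
            Xc, yc, Xv, yv = X[:-12], y[:-12], X[-12:], y[-12:]
            cfg = SpaConfig(k_min=1, k_max=n_bands)
            Z, _, _ = standardize(Xc)
            chains = [projection_chain(Z, s, n_bands)
                      for s in range(n_bands)]
            result = press_evaluate(chains, Xc, yc, Xv, yv, cfg)
            assert result.press == pytest.approx(
                _brute_force_prefix_press(chains, Xc, yc, Xv, yv, cfg))

    def test_press_by_size_monotone_bookkeeping(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] - X[:, 3] + 0.1 * rng.normal(size=40)
        Xc, yc, Xv, yv = X[:-12], y[:-12], X[-12:], y[-12:]
        cfg = SpaConfig(k_min=1, k_max=6)
        Z, _, _ = standardize(Xc)
        chains = [projection_chain(Z, s, 6) for s in range(6)]
        result = press_evaluate(chains, Xc, yc, Xv, yv, cfg)
        assert result.press == min(result.press_by_size.values())


class TestFtestPrune:
    def test_prune_never_grows_subset(self, rng):
        X = rng.normal(size=(60, 8))
        y = 2 * X[:, 1] + 0.05 * rng.normal(size=60)
        result = select_wavelengths(X, y, SpaConfig(k_min=1, k_max=8))
        assert 1 in result.selected  # the truly informative band survives
        assert len(result.selected) <= 8
        assert set(result.relevance) >= set()

    def test_irrelevant_bands_pruned(self, rng):
        # y depends on band 1 only; pruning should drop most noise bands.
        X = rng.normal(size=(80, 8))
        y = 3 * X[:, 1] + 0.02 * rng.normal(size=80)
        result = select_wavelengths(X, y, SpaConfig(k_min=1, k_max=8))
        assert len(result.selected) <= 3


class TestSelectWavelengths:
    def test_reproducible_for_seed(self, rng):
        X = rng.normal(size=(60, 10))
        y = X[:, 2] - X[:, 7] + 0.1 * rng.normal(size=60)
        a = select_wavelengths(X, y, SpaConfig(k_min=2, k_max=6), seed=4)
        b = select_wavelengths(X, y, SpaConfig(k_min=2, k_max=6), seed=4)
        assert a.selected == b.selected
        assert a.press == b.press

    def test_recovers_informative_pair(self, rng):
        # Full-depth chains guarantee both informative bands appear in some
        # scored prefix; PRESS then keeps them and pruning ranks them first.
        X = rng.normal(size=(80, 10))
        y = X[:, 2] - X[:, 7] + 0.05 * rng.normal(size=80)
        result = select_wavelengths(X, y, SpaConfig(k_min=2, k_max=10))
        assert {2, 7} <= set(result.selected)

    def test_json_export(self, tmp_path, rng):
        X = rng.normal(size=(40, 5))
        y = X[:, 0] + 0.1 * rng.normal(size=40)
        result = select_wavelengths(X, y, SpaConfig(k_min=1, k_max=4))
        grid = np.linspace(400, 800, 5)
        result.to_json(tmp_path / "spa.json", grid_values=grid)
        import json
        payload = json.loads((tmp_path / "spa.json").read_text())
        assert payload["selected_indices"] == result.selected
        assert len(payload["selected_nm"]) == len(result.selected)
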