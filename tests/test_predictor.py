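"""Predictor: standardization, metrics, MLP training protocol, CV search."""

import numpy as np
import pytest

from gsgmol.predictor import (
    DEFAULT_GRID,
    LogPRegressor,
    evaluate,
    grid_search_cv,
    load_model,
    save_model,
    standardize_fit,
)
from gsgmol.scattering import GSGConfig
from gsgmol.synthetic import FixtureSpec, generate_regression

SMALL_NET = dict(hidden_layers=2, hidden_size=32, max_epochs=40,
                 batch_size=64, dropout=0.1)


class TestStandardize:
    def test_two_point_column(self):
        scaler = standardize_fit(np.array([[1.0], [3.0]]))
        assert scaler.mean_[0] == 2.0
        out = scaler.transform([[1.0], [3.0]]).ravel()
        assert np.allclose(out, [-1.0, 1.0])

    def test_constant_column_maps_to_zero_and_flagged(self):
        X = np.array([[5.0, 1.0], [5.0, 2.0], [5.0, 3.0]])
        scaler = standardize_fit(X)
        assert scaler.zero_variance_mask_.tolist() == [True, False]
        assert np.allclose(scaler.transform(X)[:, 0], 0.0)

    def test_random_matrix_recomputation_oracle(self, rng):
        X = rng.normal(size=(100, 10)) * rng.uniform(0.5, 5, size=10)
        scaler = standardize_fit(X)
        Z = scaler.transform(X)
        assert np.abs(Z.mean(axis=0)).max() < 1e-10
        assert np.allclose(Z.std(axis=0), 1.0, atol=1e-10)
        # direct-formula oracle
        assert np.allclose(Z, (X - X.mean(0)) / X.std(0), atol=1e-10)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            standardize_fit(np.ones((1, 3)))


class TestEvaluate:
    def test_perfect_fit(self):
        m = evaluate([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert (m.rmse, m.mae) == (0.0, 0.0)
        assert m.r2 == pytest.approx(1.0)
        assert m.r2_cod == pytest.approx(1.0)

    def test_unit_errors_closed_form(self):
        m = evaluate([1.0, -1.0], [0.0, 0.0])
        assert m.rmse == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)

    def test_random_pairs_match_direct_formulas(self, rng):
        p, o = rng.normal(size=1000), rng.normal(size=1000)
        m = evaluate(p, o)
        assert m.rmse == pytest.approx(np.sqrt(np.mean((p - o) ** 2)), abs=1e-12)
        assert m.mae == pytest.approx(np.mean(np.abs(p - o)), abs=1e-12)
        r = np.corrcoef(p, o)[0, 1]
        assert m.r2 == pytest.approx(r * r, abs=1e-12)
        assert m.rmse >= m.mae >= 0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate([1.0, 2.0], [1.0])


class TestLogPRegressor:
    def test_constant_target_learned(self, rng):
        # Adam moves each weight by at most ~lr per step, so fitting a
        # constant offset needs enough steps under the decaying schedule
        X = rng.normal(size=(200, 5))
        y = np.full(200, 1.7)
        model = LogPRegressor(random_state=0, hidden_layers=2, hidden_size=32,
                              dropout=0.0, max_epochs=200,
                              batch_size=64).fit(X, y)
        pred = model.predict(rng.normal(size=(50, 5)))
        assert np.abs(pred - 1.7).max() < 0.05

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(120, 6))
        y = X[:, 0] + 0.1 * rng.normal(size=120)
        m1 = LogPRegressor(random_state=7, **SMALL_NET).fit(X, y)
        m2 = LogPRegressor(random_state=7, **SMALL_NET).fit(X, y)
        for w1, w2 in zip(m1.coefs_, m2.coefs_):
            assert np.array_equal(w1, w2)
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_learning_rate_schedule(self, rng):
        X = rng.normal(size=(64, 3))
        y = rng.normal(size=64)
        model = LogPRegressor(random_state=0, hidden_layers=2, hidden_size=8,
                              max_epochs=46).fit(X, y)
        lrs = model.lr_schedule_
        for e, lr in enumerate(lrs):
            assert lr == pytest.approx(0.005 * 0.5 ** (e // 15))

    def test_feature_count_mismatch_refused(self, rng):
        X = rng.normal(size=(50, 4))
        model = LogPRegressor(random_state=0, **SMALL_NET).fit(
            X, rng.normal(size=50))
        with pytest.raises(ValueError, match="feature"):
            model.predict(rng.normal(size=(5, 6)))

    def test_linear_signal_recovered(self, rng):
        X = rng.normal(size=(400, 8))
        y = X @ rng.normal(size=8) + 0.05 * rng.normal(size=400)
        model = LogPRegressor(random_state=1, hidden_layers=2, hidden_size=64,
                              dropout=0.0, max_epochs=120,
                              batch_size=64).fit(X[:300], y[:300])
        m = evaluate(model.predict(X[300:]), y[300:])
        assert m.r2_cod > 0.9


class TestGridSearch:
    def test_default_grid_has_24_points(self):
        from sklearn.model_selection import ParameterGrid

        assert len(list(ParameterGrid(DEFAULT_GRID))) == 24

    def test_singleton_grid_returns_that_point(self, rng):
        X = rng.normal(size=(60, 4))
        y = X[:, 0]
        grid = {"hidden_layers": [2], "hidden_size": [16], "dropout": [0.0]}
        _, best, table = grid_search_cv(X, y, param_grid=grid, random_state=0,
                                        max_epochs=10, batch_size=32)
        assert best == {"hidden_layers": 2, "hidden_size": 16, "dropout": 0.0}
        assert len(table) == 1

    def test_fewer_rows_than_folds_rejected(self, rng):
        with pytest.raises(ValueError):
            grid_search_cv(rng.normal(size=(3, 2)), np.zeros(3))

    def test_fold_hygiene_standardizer_from_train_folds_only(self, rng):
        # the standardizer lives inside the estimator, so a fold model's
        # scaler must reproduce the training-fold mean, not the full mean
        from sklearn.model_selection import KFold

        X = rng.normal(size=(100, 3)) + 5.0
        y = rng.normal(size=100)
        train_idx, val_idx = next(iter(
            KFold(5, shuffle=True, random_state=0).split(X)))
        model = LogPRegressor(random_state=0, hidden_layers=2, hidden_size=8,
                              max_epochs=5).fit(X[train_idx], y[train_idx])
        assert np.allclose(model.scaler_.mean_, X[train_idx].mean(axis=0))
        assert not np.allclose(model.scaler_.mean_, X.mean(axis=0))


class TestPersistence:
    def test_save_load_round_trip(self, rng, tmp_path):
        X = rng.normal(size=(80, 5))
        y = X[:, 0] - X[:, 3]
        model = LogPRegressor(random_state=3, **SMALL_NET).fit(X, y)
        path = tmp_path / "model.json"
        save_model(model, path, metadata={"provider": "fallback"})
        loaded, meta = load_model(path)
        assert meta["provider"] == "fallback"
        assert np.allclose(loaded.predict(X), model.predict(X), atol=1e-12)


class TestOnSyntheticFeatures:
    def test_noiseless_linear_probe_is_exact(self):
        from sklearn.linear_model import LinearRegression

        spec = FixtureSpec(n_molecules=80, noise_sd=0.0, seed=21)
        X, y, _ = generate_regression(spec, GSGConfig(J=2, Q=2))
        keep = X.std(axis=0) > 0
        probe = LinearRegression().fit(X[:, keep], y)
        rmse = np.sqrt(np.mean((probe.predict(X[:, keep]) - y) ** 2))
        assert rmse < 1e-6
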