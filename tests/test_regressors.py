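"""Metrics oracle and the three regression branches on learnable toys."""

import numpy as np
import pandas as pd
import pytest

from pkaqsar.regressors import (
    compute_metrics,
    evaluate_on_test,
    load_model,
    predict,
    save_model,
    train_dnn,
    train_svm,
    train_xgb,
)


class TestMetrics:
    def test_identity(self):
        m = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["r2"] == 1.0 and m["rmse"] == 0.0

    def test_mean_prediction(self):
        m = compute_metrics([1, 2, 3], [2, 2, 2])
        assert m["rmse"] == pytest.approx(0.8165, abs=1e-4)
        assert m["r2"] == pytest.approx(0.0)

    def test_constant_offset(self):
        m = compute_metrics([1, 2, 3], [2, 3, 4])
        assert m["rmse"] == pytest.approx(1.0)
        assert m["r2"] == pytest.approx(-0.5)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_row_order_invariance(self, rng):
        obs = rng.normal(size=20)
        pred = obs + rng.normal(scale=0.3, size=20)
        perm = rng.permutation(20)
        a = compute_metrics(obs, pred)
        b = compute_metrics(obs[perm], pred[perm])
        assert a["rmse"] == pytest.approx(b["rmse"]) and a["r2"] == pytest.approx(b["r2"])


def _binary_linear_data(n=200, p=5, noise=0.1, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.integers(0, 2, size=(n, p)).astype(float), columns=[f"b{i}" for i in range(p)]
    )
    coefs = np.array([3.0, -2.0, 1.5, 0.5, -1.0])[:p]
    y = 5.0 + X.to_numpy() @ coefs + rng.normal(scale=noise, size=n)
    return X, y


class TestSVM:
    def test_interpolation_limit(self):
        X = pd.DataFrame({"a": np.tile([0.0, 1.0], 5), "b": np.tile([1.0, 0.0], 5)})
        y = np.tile([2.0, 8.0], 5)
        model = train_svm(X, y, cv_folds=2, param_grid={"C": [1e4], "gamma": [1.0], "epsilon": [0.01]})
        assert model.metrics.rmse_fit < 0.05

    def test_recovers_linear_binary_signal(self):
        X, y = _binary_linear_data(n=200, seed=1)
        model = train_svm(X[:150], y[:150], seed=1)
        m = evaluate_on_test(model, X[150:], y[150:])
        assert m.r2_test > 0.9

    def test_degenerate_target_errors(self):
        X, _ = _binary_linear_data(n=20)
        with pytest.raises(ValueError):
            train_svm(X, np.full(20, 4.2))

    def test_q2_not_above_fit_r2(self):
        X, y = _binary_linear_data(n=120, noise=0.5, seed=2)
        model = train_svm(X, y, seed=2)
        assert model.metrics.q2_cv <= model.metrics.r2_fit + 0.05


class TestXGB:
    def test_constant_like_prediction_on_flat_target(self):
        X, _ = _binary_linear_data(n=60, seed=3)
        y = np.full(60, 7.0)
        y[0] = 7.000001  # dodge the degenerate-target guard, stay flat
        model = train_xgb(X, y, param_grid={"n_estimators": [20], "max_depth": [2],
                                            "learning_rate": [0.3]}, seed=3)
        assert model.metrics.rmse_fit < 0.01

    def test_importances_identify_generative_features(self):
        X, y = _binary_linear_data(n=300, p=5, seed=4)
        for i in range(5, 10):  # pure-noise columns
            X[f"n{i}"] = np.random.default_rng(i).integers(0, 2, 300).astype(float)
        model = train_xgb(X, y, seed=4)
        top = set(model.importances().head(5).index)
        assert top == {"b0", "b1", "b2", "b3", "b4"}

    def test_test_metrics_reported(self):
        X, y = _binary_linear_data(n=200, seed=5)
        model = train_xgb(X[:150], y[:150], seed=5)
        m = evaluate_on_test(model, X[150:], y[150:])
        assert m.r2_test > 0.9 and m.n_test == 50


class TestDNN:
    def test_learns_single_feature_linear_target(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"x": rng.uniform(-1, 1, 300)})
        y = 2.0 * X["x"].to_numpy() + 3.0
        model = train_dnn(X[:240], y[:240], hidden_layer_sizes=(32, 32), max_iter=800,
                          param_grid={"alpha": [1e-5], "learning_rate_init": [1e-2]}, seed=6)
        m = evaluate_on_test(model, X[240:], y[240:])
        assert m.rmse_test < 0.3

    def test_same_seed_identical_predictions(self):
        X, y = _binary_linear_data(n=100, seed=7)
        grid = {"alpha": [1e-4], "learning_rate_init": [1e-3]}
        m1 = train_dnn(X, y, hidden_layer_sizes=(16,), max_iter=100, param_grid=grid, seed=7)
        m2 = train_dnn(X, y, hidden_layer_sizes=(16,), max_iter=100, param_grid=grid, seed=7)
        np.testing.assert_array_equal(predict(m1, X), predict(m2, X))


class TestPredictIO:
    def test_save_load_round_trip(self, tmp_path):
        X, y = _binary_linear_data(n=80, seed=8)
        model = train_svm(X, y, param_grid={"C": [10.0], "gamma": ["scale"], "epsilon": [0.1]},
                          seed=8)
        path = tmp_path / "svm.joblib"
        save_model(model, path)
        reloaded = load_model(path)
        np.testing.assert_array_equal(predict(model, X), predict(reloaded, X))

    def test_feature_mismatch_errors(self):
        X, y = _binary_linear_data(n=40, seed=9)
        model = train_svm(X, y, param_grid={"C": [1.0], "gamma": ["scale"], "epsilon": [0.1]})
        with pytest.raises(ValueError):
            predict(model, X.rename(columns={"b0": "zzz"}))

    def test_column_order_alignment(self):
        X, y = _binary_linear_data(n=60, seed=10)
        model = train_svm(X, y, param_grid={"C": [1.0], "gamma": ["scale"], "epsilon": [0.1]})
        shuffled = X[list(X.columns[::-1])]
        np.testing.assert_array_equal(predict(model, X), predict(model, shuffled))
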