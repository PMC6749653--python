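"""pKa regression branches: support vectors, gradient boosting, neural net.

Acidic and basic targets are always modeled separately; all branches are
tuned by cross-validated RMSE on the training split and report R² on the
fit, Q² from out-of-fold predictions, and R²/RMSE on the held-out test
split so the three branches are comparable on paired splits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import GridSearchCV, KFold, RepeatedKFold, cross_val_predict
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .featurize import FeatureMatrix

__all__ = [
    "EvalMetrics",
    "RegressorModel",
    "compute_metrics",
    "train_svm",
    "train_xgb",
    "train_dnn",
    "predict",
    "save_model",
    "load_model",
]


@dataclass
class EvalMetrics:
    r2_fit: float | None = None
    rmse_fit: float | None = None
    q2_cv: float | None = None
    rmse_cv: float | None = None
    r2_test: float | None = None
    rmse_test: float | None = None
    n_train: int = 0
    n_test: int = 0


def compute_metrics(observed: Sequence[float], predicted: Sequence[float]) -> dict[str, float]:
    """RMSE and coefficient of determination about the observed mean.

    R² = 1 − SS_res/SS_tot; raises ValueError when the observed vector
    has zero variance (R² undefined).
    """
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least 2 points")
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("observed values have zero variance; R² undefined")
    ss_res = float(((obs - pred) ** 2).sum())
    rmse = float(np.sqrt(((obs - pred) ** 2).mean()))
    return {"r2": 1.0 - ss_res / ss_tot, "rmse": rmse}


@dataclass
class RegressorModel:
    algorithm: str  # svm | xgb | dnn
    target: str  # acidic | basic | combined
    feature_names: list[str]
    hyperparams: dict[str, Any]
    estimator: Any
    metrics: EvalMetrics = field(default_factory=EvalMetrics)
    feature_spec: dict[str, Any] = field(default_factory=dict)
    seed: int = 0

    def importances(self) -> pd.Series | None:
        est = self.estimator
        if hasattr(est, "feature_importances_"):
            return pd.Series(est.feature_importances_, index=self.feature_names).sort_values(
                ascending=False
            )
        return None


def _as_frame(fm) -> pd.DataFrame:
    return fm.frame if isinstance(fm, FeatureMatrix) else pd.DataFrame(fm)


def _check_target(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise ValueError("degenerate single-valued target")


def _finalize(model: RegressorModel, X: np.ndarray, y: np.ndarray, cv) -> RegressorModel:
    """Fill fit metrics and Q² from out-of-fold predictions."""
    est = model.estimator
    fit_pred = est.predict(X)
    m_fit = compute_metrics(y, fit_pred)
    oof = cross_val_predict(est, X, y, cv=cv)
    m_cv = compute_metrics(y, oof)
    model.metrics.r2_fit = m_fit["r2"]
    model.metrics.rmse_fit = m_fit["rmse"]
    model.metrics.q2_cv = m_cv["r2"]
    model.metrics.rmse_cv = m_cv["rmse"]
    model.metrics.n_train = len(y)
    return model


def evaluate_on_test(model: RegressorModel, fm_test, y_test) -> EvalMetrics:
    pred = predict(model, fm_test)
    m = compute_metrics(np.asarray(y_test, dtype=float), pred)
    model.metrics.r2_test = m["r2"]
    model.metrics.rmse_test = m["rmse"]
    model.metrics.n_test = len(pred)
    return model.metrics


DEFAULT_SVM_GRID: Mapping[str, list] = {
    "C": [1.0, 10.0, 100.0],
    "gamma": ["scale", 0.01, 0.001],
    "epsilon": [0.1, 0.5],
}

DEFAULT_XGB_GRID: Mapping[str, list] = {
    "n_estimators": [200, 400],
    "max_depth": [4, 6],
    "learning_rate": [0.1],
}

DEFAULT_DNN_GRID: Mapping[str, list] = {
    "alpha": [1e-4, 1e-3],
    "learning_rate_init": [1e-3],
}


def train_svm(
    fm_train,
    pka_values,
    cv_folds: int = 5,
    param_grid: Mapping[str, list] | None = None,
    seed: int = 0,
    target: str = "acidic",
    feature_spec: dict | None = None,
) -> RegressorModel:
    """Epsilon-SVR with RBF kernel, grid-tuned on CV RMSE."""
    frame = _as_frame(fm_train)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(pka_values, dtype=float)
    _check_target(y)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    grid = GridSearchCV(
        SVR(kernel="rbf"),
        dict(param_grid or DEFAULT_SVM_GRID),
        scoring="neg_root_mean_squared_error",
        cv=cv,
        n_jobs=1,
    )
    grid.fit(X, y)
    model = RegressorModel(
        "svm", target, list(frame.columns), dict(grid.best_params_), grid.best_estimator_,
        feature_spec=feature_spec or {}, seed=seed,
    )
    return _finalize(model, X, y, cv)


def train_xgb(
    fm_train,
    pka_values,
    cv_folds: int = 5,
    cv_repeats: int = 1,
    param_grid: Mapping[str, list] | None = None,
    seed: int = 0,
    target: str = "acidic",
    feature_spec: dict | None = None,
) -> RegressorModel:
    """Gradient-boosted trees tuned on repeated-CV RMSE; importances exposed."""
    frame = _as_frame(fm_train)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(pka_values, dtype=float)
    _check_target(y)
    cv = RepeatedKFold(n_splits=cv_folds, n_repeats=cv_repeats, random_state=seed)
    base = XGBRegressor(
        tree_method="hist", n_jobs=1, random_state=seed, verbosity=0, reg_lambda=1.0
    )
    grid = GridSearchCV(
        base,
        dict(param_grid or DEFAULT_XGB_GRID),
        scoring="neg_root_mean_squared_error",
        cv=cv,
        n_jobs=1,
    )
    grid.fit(X, y)
    model = RegressorModel(
        "xgb", target, list(frame.columns), dict(grid.best_params_), grid.best_estimator_,
        feature_spec=feature_spec or {}, seed=seed,
    )
    return _finalize(model, X, y, KFold(n_splits=cv_folds, shuffle=True, random_state=seed))


def train_dnn(
    fm_train,
    pka_values,
    cv_folds: int = 5,
    param_grid: Mapping[str, list] | None = None,
    hidden_layer_sizes: tuple[int, ...] = (256, 256, 256),
    max_iter: int = 500,
    seed: int = 0,
    target: str = "acidic",
    feature_spec: dict | None = None,
) -> RegressorModel:
    """Fully connected net: three hidden layers of 256 ReLU units, Adam,
    early stopping, L2 regularization; tuned by CV RMSE.

    Inputs are expected pre-scaled (see :mod:`pkaqsar.featurize`).
    Deterministic for a fixed seed.
    """
    frame = _as_frame(fm_train)
    X = frame.to_numpy(dtype=float)
    y = np.asarray(pka_values, dtype=float)
    _check_target(y)
    cv = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    base = MLPRegressor(
        hidden_layer_sizes=hidden_layer_sizes,
        activation="relu",
        solver="adam",
        early_stopping=True,
        n_iter_no_change=20,
        max_iter=max_iter,
        random_state=seed,
    )
    grid = GridSearchCV(
        base,
        dict(param_grid or DEFAULT_DNN_GRID),
        scoring="neg_root_mean_squared_error",
        cv=cv,
        n_jobs=1,
    )
    grid.fit(X, y)
    model = RegressorModel(
        "dnn", target, list(frame.columns), dict(grid.best_params_), grid.best_estimator_,
        feature_spec=feature_spec or {}, seed=seed,
    )
    return _finalize(model, X, y, cv)


def predict(model: RegressorModel, fm) -> np.ndarray:
    """Predict pKa values; columns are aligned to the training order."""
    frame = _as_frame(fm)
    missing = [c for c in model.feature_names if c not in frame.columns]
    if missing:
        raise ValueError(f"feature spec mismatch; {len(missing)} training columns absent")
    X = frame[model.feature_names].to_numpy(dtype=float)
    out = np.asarray(model.estimator.predict(X), dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite prediction encountered")
    return out


def save_model(model: RegressorModel, path) -> None:
    joblib.dump(model, path)


def load_model(path) -> RegressorModel:
    return joblib.load(path)
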