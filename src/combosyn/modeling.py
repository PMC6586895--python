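"""Regression backends, the boosting tuning protocol, and binarization.

Five model families are supported for synergy-score regression: ordinary
least squares, the Lasso (regularization strength by internal CV), an
epsilon-insensitive support vector machine with an RBF kernel, random
forest, and gradient-boosted trees (xgboost).  Two boosting presets ship
with the package: ``paper-tuned`` (n_estimators=500, max_depth=8,
subsample=0.75, colsample_bytree=1.0), the parameters found by the
coordinate sweep implemented in :func:`tune_xgboost`, and ``paper-default``
(n_estimators=250, max_depth=8, subsample=1.0, colsample_bytree=1.0), the
comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor
from sklearn.linear_model import LassoCV, LinearRegression, LogisticRegression
from sklearn.model_selection import KFold
from sklearn.svm import SVC, SVR

from .data_model import FeatureMatrix
from .errors import ConfigError

MODEL_KINDS = ("linear", "lasso", "svm", "random_forest", "xgboost")

XGB_PRESETS: dict[str, dict[str, float]] = {
    "paper-tuned": {"n_estimators": 500, "max_depth": 8,
                    "subsample": 0.75, "colsample_bytree": 1.0},
    "paper-default": {"n_estimators": 250, "max_depth": 8,
                      "subsample": 1.0, "colsample_bytree": 1.0},
}


@dataclass
class ModelSpec:
    kind: str
    params: dict = field(default_factory=dict)
    task: str = "regression"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ConfigError(f"unknown model kind {self.kind!r}; "
                              f"choose from {MODEL_KINDS}")
        if self.task not in ("regression", "classification"):
            raise ConfigError(f"unknown task {self.task!r}")

    @classmethod
    def xgboost_preset(cls, preset: str = "paper-tuned", task: str = "regression",
                       seed: int = 0) -> "ModelSpec":
        if preset not in XGB_PRESETS:
            raise ConfigError(f"unknown preset {preset!r}")
        return cls(kind="xgboost", params=dict(XGB_PRESETS[preset]),
                   task=task, seed=seed)


@dataclass
class TuningGrid:
    axes: dict[str, list]
    fixed: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.axes or any(len(v) == 0 for v in self.axes.values()):
            raise ConfigError("tuning grid axes must be non-empty")


class FittedModel:
    """Uniform predict/gain surface over the five backends."""

    def __init__(self, spec: ModelSpec, estimator, feature_names: list[str]):
        self.spec = spec
        self.estimator = estimator
        self.feature_names = feature_names

    def predict(self, X) -> np.ndarray:
        X = _as_array(X, self.feature_names)
        if self.spec.task == "classification":
            if hasattr(self.estimator, "predict_proba"):
                return self.estimator.predict_proba(X)[:, 1]
            return self.estimator.decision_function(X)
        return np.asarray(self.estimator.predict(X), dtype=float)

    @property
    def is_tree_model(self) -> bool:
        return self.spec.kind in ("random_forest", "xgboost")

    def raw_gains(self) -> pd.Series:
        """Total split gain per feature (tree models only); unused -> 0."""
        from .errors import UnsupportedModelError

        if self.spec.kind == "xgboost":
            booster = self.estimator.get_booster()
            scores = booster.get_score(importance_type="total_gain")
            gains = pd.Series(0.0, index=self.feature_names)
            for key, val in scores.items():
                # booster names features f0, f1, ... when fit on arrays
                name = self.feature_names[int(key[1:])] if key.startswith("f") \
                    and key[1:].isdigit() else key
                gains[name] = val
            return gains
        if self.spec.kind == "random_forest":
            return pd.Series(self.estimator.feature_importances_,
                             index=self.feature_names)
        raise UnsupportedModelError(
            f"{self.spec.kind!r} models do not export split gains")


def _as_array(X, feature_names: list[str] | None = None) -> np.ndarray:
    if isinstance(X, FeatureMatrix):
        X = X.values
    if isinstance(X, pd.DataFrame):
        if feature_names is not None:
            X = X[feature_names]
        return X.to_numpy(dtype=float)
    return np.asarray(X, dtype=float)


def _make_estimator(spec: ModelSpec):
    params = dict(spec.params)
    if spec.task == "classification":
        if spec.kind == "linear":
            return LogisticRegression(max_iter=2000, **params)
        if spec.kind == "lasso":
            return LogisticRegression(penalty="l1", solver="liblinear",
                                      max_iter=2000, **params)
        if spec.kind == "svm":
            return SVC(kernel=params.pop("kernel", "rbf"),
                       probability=False, **params)
        if spec.kind == "random_forest":
            params.setdefault("n_estimators", 100)
            return RandomForestClassifier(random_state=spec.seed, **params)
        from xgboost import XGBClassifier

        params.setdefault("learning_rate", 0.1)
        return XGBClassifier(random_state=spec.seed, n_jobs=1,
                             tree_method="hist", **params)
    if spec.kind == "linear":
        return LinearRegression(**params)
    if spec.kind == "lasso":
        params.setdefault("cv", 5)
        return LassoCV(random_state=spec.seed, **params)
    if spec.kind == "svm":
        return SVR(kernel=params.pop("kernel", "rbf"), **params)
    if spec.kind == "random_forest":
        params.setdefault("n_estimators", 100)
        return RandomForestRegressor(random_state=spec.seed, **params)
    from xgboost import XGBRegressor

    params.setdefault("learning_rate", 0.1)
    return XGBRegressor(random_state=spec.seed, n_jobs=1,
                        tree_method="hist", **params)


def fit(spec: ModelSpec, X, y) -> FittedModel:
    """Fit one backend; deterministic given spec.seed."""
    if isinstance(X, FeatureMatrix):
        names = list(X.values.columns)
        arr = X.values.to_numpy(dtype=float)
    elif isinstance(X, pd.DataFrame):
        names = list(X.columns)
        arr = X.to_numpy(dtype=float)
    else:
        arr = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(arr.shape[1])]
    y = np.asarray(y, dtype=float)
    if arr.shape[0] != y.size:
        raise ConfigError(f"X has {arr.shape[0]} rows but y has {y.size}")
    if not np.isfinite(arr).all():
        raise ConfigError("feature matrix contains non-finite values")
    est = _make_estimator(spec)
    est.fit(arr, y.astype(int) if spec.task == "classification" else y)
    return FittedModel(spec=spec, estimator=est, feature_names=names)


def binarize(y: Sequence[float], threshold: float = 20.0) -> np.ndarray:
    """1 iff the synergy score strictly exceeds the threshold."""
    return (np.asarray(y, dtype=float) > threshold).astype(int)


def _cv_mse(params: Mapping[str, float], X: np.ndarray, y: np.ndarray,
            cv_folds: int, seed: int) -> float:
    spec = ModelSpec(kind="xgboost", params=dict(params), seed=seed)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    errs = []
    for train, test in kf.split(X):
        model = fit(spec, X[train], y[train])
        pred = model.predict(X[test])
        errs.append(float(np.mean((pred - y[test]) ** 2)))
    return float(np.mean(errs))


def tune_xgboost(X, y, grid: TuningGrid, cv_folds: int = 5,
                 seed: int = 0, n_passes: int = 2) -> dict[str, float]:
    """Coordinate sweep over the four boosting parameters.

    Holding the other parameters at their current values, each axis is swept
    in turn and the CV-error argmin retained; the sweep is repeated
    ``n_passes`` times (the second pass re-sweeps with the first pass's best
    depth fixed, mirroring the two-stage search that produced the
    paper-tuned preset).  The returned parameters attain the minimum CV
    error among all evaluated points.
    """
    X = _as_array(X)
    y = np.asarray(y, dtype=float)
    current = {axis: values[0] for axis, values in grid.axes.items()}
    current.update(grid.fixed)
    evaluated: dict[tuple, float] = {}

    def score(params: Mapping[str, float]) -> float:
        key = tuple(sorted(params.items()))
        if key not in evaluated:
            evaluated[key] = _cv_mse(params, X, y, cv_folds, seed)
        return evaluated[key]

    for _ in range(n_passes):
        for axis, values in grid.axes.items():
            best_val, best_err = current[axis], np.inf
            for v in values:
                trial = dict(current)
                trial[axis] = v
                err = score(trial)
                if err < best_err:
                    best_val, best_err = v, err
            current[axis] = best_val  # fix before sweeping the next axis
    best_key = min(evaluated, key=evaluated.get)
    return dict(best_key)
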