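"""Adapters for point-prediction regressors.

A predictive-distribution method needs three things from its underlying
learner: a fitted point predictor, a bagged ensemble of bootstrap
replicas (for variance-based error estimation), and out-of-fold
cross-validated predictions on the training set (for uniform-CV and
local-error estimation).  This module provides a uniform contract over
scikit-learn regressors for all three, plus the descriptor
standardisation shared with the distance computations.

Hyperparameter tuning always happens inside the training partition:
``double_loop_cv`` tunes within each outer-training fold using an inner
cross-validation, so the out-of-fold RMSE is an unbiased estimate of the
generalisation error.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.dummy import DummyRegressor
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Ridge
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

logger = logging.getLogger(__name__)


class DescriptorScaler:
    """Zero-mean / unit-variance scaling with zero-variance columns dropped.

    Fit on training descriptors only; the same transform is applied to
    queries for both model fitting and distance computations.
    """

    def fit(self, X: np.ndarray) -> "DescriptorScaler":
        X = np.asarray(X, dtype=float)
        self.mean_ = X.mean(axis=0)
        self.sd_ = X.std(axis=0, ddof=0)
        self.keep_ = self.sd_ > 0
        if not np.any(self.keep_):
            raise ValueError("all descriptors have zero variance")
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.mean_.shape[0]:
            raise ValueError(
                f"descriptor length mismatch: got {X.shape[1]}, "
                f"expected {self.mean_.shape[0]}"
            )
        Z = (X[:, self.keep_] - self.mean_[self.keep_]) / self.sd_[self.keep_]
        return Z

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        return self.fit(X).transform(X)


@dataclass(frozen=True)
class RegressorSpec:
    """Algorithm name plus hyperparameter grid and fixed parameters.

    ``param_grid`` is searched by inner cross-validation during fitting;
    an empty grid means no tuning.  Tuning only ever sees the data
    passed to ``fit``.
    """

    algorithm: str
    param_grid: Mapping[str, list] = field(default_factory=dict)
    fixed_params: Mapping[str, Any] = field(default_factory=dict)
    tuning_folds: int = 7


# Registered learner factories.  Each maps (fixed_params, seed) to an
# unfitted scikit-learn regressor.  The RF/SVM/KNN/PLS defaults follow
# common practice for descriptor-based property models: 250-tree forests
# with nodesize 1 and tuned mtry; RBF-kernel SVMs with cost 2 and a
# small gamma grid; distance-weighted k-NN with cross-validated k.
def _make_rf(params: Mapping[str, Any], seed: int | None) -> RandomForestRegressor:
    p = {"n_estimators": 250, "min_samples_leaf": 1, **params}
    return RandomForestRegressor(random_state=seed, **p)


def _make_svm(params: Mapping[str, Any], seed: int | None) -> SVR:
    p = {"kernel": "rbf", "C": 2.0, **params}
    return SVR(**p)


def _make_knn(params: Mapping[str, Any], seed: int | None) -> KNeighborsRegressor:
    p = {"weights": "distance", **params}
    return KNeighborsRegressor(**p)


def _make_pls(params: Mapping[str, Any], seed: int | None) -> PLSRegression:
    return PLSRegression(**params)


def _make_ridge(params: Mapping[str, Any], seed: int | None) -> Ridge:
    return Ridge(**params)


def _make_mean(params: Mapping[str, Any], seed: int | None) -> DummyRegressor:
    return DummyRegressor(strategy="mean")


REGISTRY: dict[str, Callable[[Mapping[str, Any], int | None], Any]] = {
    "rf": _make_rf,
    "svm": _make_svm,
    "knn": _make_knn,
    "pls": _make_pls,
    "ridge": _make_ridge,
    "mean": _make_mean,
}

# Default tuning grids mirroring the learners' usual protocols.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "svm": {"gamma": [2.0**-8, 2.0**-7, 2.0**-6]},
    "knn": {"n_neighbors": [1, 3, 5, 9, 15]},
    "pls": {"n_components": [2, 3, 5, 8]},
    "rf": {},  # mtry tuned via OOB below when requested
    "ridge": {},
    "mean": {},
}


def make_spec(algorithm: str, **fixed_params: Any) -> RegressorSpec:
    """Spec with the registered default grid for ``algorithm``."""
    if algorithm not in REGISTRY:
        raise KeyError(f"unknown algorithm {algorithm!r}; known: {sorted(REGISTRY)}")
    return RegressorSpec(
        algorithm=algorithm,
        param_grid=DEFAULT_GRIDS.get(algorithm, {}),
        fixed_params=fixed_params,
    )


class FittedModel:
    """A fitted point predictor with its chosen hyperparameters."""

    def __init__(self, estimator: Any, spec: RegressorSpec, best_params: dict):
        self._est = estimator
        self.spec = spec
        self.best_params = best_params

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self._est.predict(np.atleast_2d(X)), dtype=float).ravel()


def _build(spec: RegressorSpec, seed: int | None) -> Any:
    try:
        factory = REGISTRY[spec.algorithm]
    except KeyError:
        raise KeyError(
            f"unknown algorithm {spec.algorithm!r}; known: {sorted(REGISTRY)}"
        ) from None
    return factory(spec.fixed_params, seed)


def fit(
    spec: RegressorSpec,
    X: np.ndarray,
    y: np.ndarray,
    seed: int | None = None,
) -> FittedModel:
    """Fit a regressor, tuning any gridded hyperparameters by inner CV."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X rows must align with y")
    if np.ptp(y) == 0:
        logger.warning("training target is constant; model will predict a constant")
    est = _build(spec, seed)
    best_params: dict = {}
    grid = {k: list(v) for k, v in spec.param_grid.items()}
    if grid:
        n_splits = min(spec.tuning_folds, X.shape[0])
        if n_splits >= 2 and X.shape[0] >= 2 * n_splits:
            cv = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
            search = GridSearchCV(est, grid, cv=cv, scoring="neg_mean_squared_error")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                search.fit(X, y)
            est = search.best_estimator_
            best_params = dict(search.best_params_)
            return FittedModel(est, spec, best_params)
        # too few rows to tune: fall through with the first grid point
        best_params = {k: v[0] for k, v in grid.items()}
        est.set_params(**best_params)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return FittedModel(est, spec, best_params)


class BaggedEnsemble:
    """Bootstrap-aggregated replicas of one learner.

    Each member is trained on a with-replacement resample of the
    training rows, the same size as the training set.  The ensemble
    point prediction is the member mean; the member spread (sample SD,
    denominator B-1) is the bagged-variance reliability index.
    """

    def __init__(self, members: list[Any], bootstrap_indices: list[np.ndarray]):
        if len(members) < 2:
            raise ValueError("a bagged ensemble needs at least 2 members")
        self.members = members
        self.bootstrap_indices = bootstrap_indices

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_predictions(self, X: np.ndarray) -> np.ndarray:
        """(n_queries, B) matrix of member predictions."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack(
            [np.asarray(m.predict(X), dtype=float).ravel() for m in self.members]
        )

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.member_predictions(X).mean(axis=1)

    def spread(self, X: np.ndarray) -> np.ndarray:
        return self.member_predictions(X).std(axis=1, ddof=1)


def fit_bagged(
    spec: RegressorSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_members: int = 100,
    seed: int | None = None,
) -> BaggedEnsemble:
    """Train ``n_members`` bootstrap replicas of the learner.

    Members are fitted with the hyperparameters fixed in the spec (no
    per-member tuning); a random forest is itself such an ensemble and
    can be used directly instead.
    """
    if n_members < 2:
        raise ValueError("n_members must be >= 2 (member spread is undefined)")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    rng = np.random.default_rng(seed)
    members = []
    indices = []
    for b in range(n_members):
        idx = rng.integers(0, n, size=n)
        est = _build(spec, seed=None if seed is None else int(seed) + b)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X[idx], y[idx])
        members.append(est)
        indices.append(idx)
    return BaggedEnsemble(members, indices)


@dataclass(frozen=True)
class CVPredictionTable:
    """Out-of-fold predictions from double-loop cross-validation.

    Every training compound is predicted exactly once, by a model (and
    tuning procedure) that never saw it.  ``residual`` is observed minus
    predicted.
    """

    table: pd.DataFrame  # columns: prediction, residual, abs_error; index = row

    @property
    def predictions(self) -> np.ndarray:
        return self.table["prediction"].to_numpy()

    @property
    def residuals(self) -> np.ndarray:
        return self.table["residual"].to_numpy()

    @property
    def abs_errors(self) -> np.ndarray:
        return self.table["abs_error"].to_numpy()

    def rmse(self) -> float:
        return float(np.sqrt(np.mean(self.residuals**2)))


def double_loop_cv(
    spec: RegressorSpec,
    X: np.ndarray,
    y: np.ndarray,
    outer_folds: int = 7,
    inner_folds: int = 7,
    seed: int | None = None,
) -> CVPredictionTable:
    """Nested cross-validation producing unbiased out-of-fold predictions.

    The outer loop holds out each fold in turn; the inner loop tunes the
    learner's hyperparameters on the remaining data only.  The RMSE of
    the resulting table estimates the model's generalisation error
    without optimistic bias from the tuning step.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if outer_folds < 2:
        raise ValueError("outer_folds must be >= 2")
    if n < outer_folds:
        raise ValueError(f"cannot split {n} rows into {outer_folds} outer folds")
    inner_spec = RegressorSpec(
        algorithm=spec.algorithm,
        param_grid=spec.param_grid,
        fixed_params=spec.fixed_params,
        tuning_folds=inner_folds,
    )
    preds = np.empty(n)
    outer = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in outer.split(X):
        model = fit(inner_spec, X[train_idx], y[train_idx], seed=seed)
        preds[test_idx] = model.predict(X[test_idx])
    residuals = y - preds
    table = pd.DataFrame(
        {
            "prediction": preds,
            "residual": residuals,
            "abs_error": np.abs(residuals),
        }
    )
    return CVPredictionTable(table)
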