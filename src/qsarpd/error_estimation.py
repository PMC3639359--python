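"""Reliability indices and their conversion into prediction errors.

Two families of error-estimation methods assign the sigma of a
predictive distribution:

Uniform methods give every query the same error:

* ``TS`` — RMSE on a held-out temporal (parameterization) test set;
* ``CV`` — RMSE of double-loop cross-validated training-set predictions.

Variable methods assign compound-specific errors from a reliability
index:

* ``D2M-EUC`` / ``D2M-MD`` — distance to model: mean Euclidean or
  Mahalanobis distance to the k nearest training compounds, mapped to an
  error through a calibrated regression;
* ``LE-*`` — local error: RMSE of the cross-validated residuals of the k
  nearest training neighbours, used directly;
* ``LEC-*`` — corrected local error: the LE score passed through the
  same calibration regression as D2M;
* ``BV`` — bagged variance: the SD of a bootstrap ensemble's member
  predictions, used directly;
* ``BVC`` — the BV score passed through the calibration regression;
* ``EM`` — error model: a second regressor trained to predict the
  absolute cross-validated error from the descriptors.

The calibration regression maps a reliability score s to an error via
sigma_pred(s) = sqrt(m*s + c) with the intercept c pinned to the square
of the assay's experimental error, so that sigma_pred equals the
experimental error at score zero.  The slope is the least-squares fit of
the squared residuals through that fixed intercept, clamped at zero.

All emitted sigmas are floored at the experimental error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .distributions import GaussianDist, DistributionPairSet, floor_sigmas, mean_kl
from .models import BaggedEnsemble, CVPredictionTable, DescriptorScaler, FittedModel

VARIABLE_TAGS = (
    "D2M-EUC", "D2M-MD", "LE-EUC", "LE-MD", "LEC-EUC", "LEC-MD", "BV", "BVC", "EM",
)
UNIFORM_TAGS = ("TS", "CV")
CALIBRATED_TAGS = ("D2M-EUC", "D2M-MD", "LEC-EUC", "LEC-MD", "BVC")
DEFAULT_K_GRID = (1, 2, 3, 5, 8, 12, 20, 50, 100, 200)


# ---------------------------------------------------------------------------
# distances

def euclidean_distance(a: np.ndarray, b: np.ndarray) -> float:
    """L2 norm of the difference of two descriptor vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


class MahalanobisMetric:
    """Mahalanobis distance with an SVD pseudo-inverse covariance.

    Descriptor covariance matrices are routinely rank-deficient
    (correlated or duplicated descriptors), so the inverse is the
    Moore-Penrose pseudo-inverse with a relative singular-value cutoff.
    Distances are computed in whitened coordinates: with S^- = U D U^T,
    the map W = D^{1/2} U^T turns the Mahalanobis distance into a plain
    Euclidean one, which keeps nearest-neighbour searches vectorised.
    """

    def __init__(self, train_X: np.ndarray, rcond: float = 1e-9):
        train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
        if train_X.shape[0] < 2:
            raise ValueError("need >= 2 training rows to estimate a covariance")
        cov = np.cov(train_X, rowvar=False)
        cov = np.atleast_2d(cov)
        # symmetric PSD: eigh gives the SVD up to sign
        w, U = np.linalg.eigh(cov)
        cutoff = rcond * w.max() if w.size else 0.0
        inv_w = np.where(w > cutoff, 1.0 / np.maximum(w, 1e-300), 0.0)
        self.whitener_ = (U * np.sqrt(inv_w)).T  # rows scaled, then project

    def whiten(self, X: np.ndarray) -> np.ndarray:
        return np.atleast_2d(np.asarray(X, dtype=float)) @ self.whitener_.T

    def pairwise(self, A: np.ndarray, B: np.ndarray) -> np.ndarray:
        return cdist(self.whiten(A), self.whiten(B))


def mahalanobis_distance(a: np.ndarray, b: np.ndarray, train_X: np.ndarray) -> float:
    """Mahalanobis distance between two vectors under the training covariance."""
    metric = MahalanobisMetric(train_X)
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError(f"vector length mismatch: {a.shape} vs {b.shape}")
    return float(metric.pairwise(a[None, :], b[None, :])[0, 0])


def _pairwise(X_query: np.ndarray, train_X: np.ndarray, metric) -> np.ndarray:
    """(n_query, n_train) distance matrix for 'euclidean' | MahalanobisMetric."""
    X_query = np.atleast_2d(np.asarray(X_query, dtype=float))
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if isinstance(metric, MahalanobisMetric):
        return metric.pairwise(X_query, train_X)
    if metric == "euclidean":
        return cdist(X_query, train_X)
    raise ValueError(f"unknown metric {metric!r}")


def _knn_indices(dists: np.ndarray, k: int) -> np.ndarray:
    """Indices of the k smallest per row; ties broken by ascending row index."""
    order = np.argsort(dists, axis=1, kind="stable")
    return order[:, :k]


def knn_mean_distance(
    x: np.ndarray,
    train_X: np.ndarray,
    k: int,
    metric="euclidean",
) -> float | np.ndarray:
    """Mean distance to the k nearest training rows (distance-to-model).

    Accepts a single query vector (returns a float) or a query matrix
    (returns an array).
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    if k < 1 or k > train_X.shape[0]:
        raise ValueError(f"k={k} out of range for {train_X.shape[0]} training rows")
    d = _pairwise(x, train_X, metric)
    idx = _knn_indices(d, k)
    out = np.take_along_axis(d, idx, axis=1).mean(axis=1)
    return float(out[0]) if single else out


def local_error(
    x: np.ndarray,
    train_X: np.ndarray,
    cv_table: CVPredictionTable,
    k: int,
    metric="euclidean",
) -> float | np.ndarray:
    """RMSE of the k nearest training neighbours' out-of-fold residuals."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    train_X = np.atleast_2d(np.asarray(train_X, dtype=float))
    residuals = np.asarray(cv_table.residuals, dtype=float)
    if residuals.shape[0] != train_X.shape[0]:
        raise ValueError("cv_table must cover every training row")
    if k < 1 or k > train_X.shape[0]:
        raise ValueError(f"k={k} out of range for {train_X.shape[0]} training rows")
    d = _pairwise(x, train_X, metric)
    idx = _knn_indices(d, k)
    out = np.sqrt((residuals[idx] ** 2).mean(axis=1))
    return float(out[0]) if single else out


def bagged_variance_score(
    ensemble: BaggedEnsemble, x: np.ndarray
) -> float | np.ndarray:
    """Sample SD of the ensemble members' predictions at a query."""
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    out = ensemble.spread(x)
    return float(out[0]) if single else out


# ---------------------------------------------------------------------------
# calibration

@dataclass(frozen=True)
class ErrorCalibration:
    """sigma_pred(s) = sqrt(m*s + c), intercept c pinned at sigma_exp^2."""

    slope: float
    intercept: float
    k: int | None = None

    def sigma(self, score: np.ndarray | float) -> np.ndarray | float:
        s = np.asarray(score, dtype=float)
        out = np.sqrt(np.maximum(self.slope * s + self.intercept, 0.0))
        return float(out) if out.ndim == 0 else out


def fit_error_regression(
    scores: Sequence[float],
    residuals: Sequence[float],
    sigma_exp: float,
    k: int | None = None,
) -> ErrorCalibration:
    """Regress squared residuals on a reliability score, intercept fixed.

    With the intercept pinned at sigma_exp^2 the least-squares slope is

        m = sum_i s_i (r_i^2 - sigma_exp^2) / sum_i s_i^2,

    clamped at zero so the calibrated error is nondecreasing in the
    score.  Raises if all scores are zero (slope undefined).
    """
    s = np.asarray(scores, dtype=float)
    r = np.asarray(residuals, dtype=float)
    if s.shape != r.shape:
        raise ValueError("scores and residuals must have equal length")
    if s.size < 10:
        raise ValueError("need at least 10 points to calibrate an error regression")
    if np.any(s < 0):
        raise ValueError("reliability scores must be nonnegative")
    denom = float(np.sum(s * s))
    if denom == 0.0:
        raise ValueError("all reliability scores are zero; slope undefined")
    c = sigma_exp * sigma_exp
    m = float(np.sum(s * (r * r - c)) / denom)
    return ErrorCalibration(slope=max(m, 0.0), intercept=c, k=k)


# ---------------------------------------------------------------------------
# estimators

@dataclass
class ErrorEstimator:
    """A fitted mapping from a prediction context to sigma_pred.

    Frozen after parameterization: the same calibration parameters (m,
    c, k) or uniform RMSE are reused for all future predictions.  Every
    emitted sigma is floored at ``sigma_floor`` (the assay's
    experimental error).
    """

    tag: str
    sigma_floor: float
    uniform_sigma: float | None = None
    calibration: ErrorCalibration | None = None
    k: int | None = None
    metric: str = "euclidean"
    scaler: DescriptorScaler | None = None
    train_Z: np.ndarray | None = None
    mahal: MahalanobisMetric | None = field(default=None, repr=False)
    cv_table: CVPredictionTable | None = field(default=None, repr=False)
    ensemble: BaggedEnsemble | None = field(default=None, repr=False)
    error_model: FittedModel | None = field(default=None, repr=False)

    def _metric_obj(self):
        return self.mahal if self.metric == "mahalanobis" else "euclidean"

    def _queries(self, X: np.ndarray) -> np.ndarray:
        Z = np.atleast_2d(np.asarray(X, dtype=float))
        if self.scaler is not None:
            Z = self.scaler.transform(Z)
        return Z

    def raw_scores(self, X: np.ndarray | None = None) -> np.ndarray:
        """The reliability index per query, before calibration/flooring."""
        tag = self.tag
        if tag in UNIFORM_TAGS:
            raise ValueError(f"{tag} is uniform; it has no reliability score")
        if tag in ("BV", "BVC"):
            return np.asarray(self.ensemble.spread(np.atleast_2d(X)), dtype=float)
        if tag == "EM":
            return np.asarray(self.error_model.predict(np.atleast_2d(X)), dtype=float)
        Z = self._queries(X)
        if tag.startswith("D2M"):
            return np.asarray(
                knn_mean_distance(Z, self.train_Z, self.k, self._metric_obj())
            )
        if tag.startswith("LE"):
            return np.asarray(
                local_error(Z, self.train_Z, self.cv_table, self.k, self._metric_obj())
            )
        raise ValueError(f"unknown estimator tag {tag!r}")

    def predict_sigma(
        self, X: np.ndarray | None = None, n: int | None = None
    ) -> np.ndarray:
        """Floored sigma_pred for each query row (or ``n`` uniform copies)."""
        if self.tag in UNIFORM_TAGS:
            if n is None:
                if X is None:
                    raise ValueError("uniform estimator needs X or n")
                n = np.atleast_2d(np.asarray(X, dtype=float)).shape[0]
            return floor_sigmas(np.full(n, self.uniform_sigma), self.sigma_floor)
        scores = self.raw_scores(X)
        if self.tag in CALIBRATED_TAGS:
            sig = self.calibration.sigma(scores)
        elif self.tag == "EM":
            sig = np.maximum(scores, 0.0)  # negative predicted |error| -> floor
        else:  # BV, LE-*: the raw score is already on the error scale
            sig = scores
        return floor_sigmas(np.asarray(sig, dtype=float), self.sigma_floor)

    def state_dict(self) -> dict:
        """Frozen calibration parameters, serialisable to JSON."""
        return {
            "tag": self.tag,
            "sigma_floor": self.sigma_floor,
            "uniform_sigma": self.uniform_sigma,
            "slope": None if self.calibration is None else self.calibration.slope,
            "intercept": None if self.calibration is None else self.calibration.intercept,
            "k": self.k,
            "metric": self.metric,
        }

    def state_json(self) -> str:
        return json.dumps(self.state_dict(), sort_keys=True)


def make_uniform_estimator(
    kind: str,
    predictions: Sequence[float],
    observations: Sequence[float],
    sigma_floor: float,
) -> ErrorEstimator:
    """Constant sigma_pred equal to the RMSE of a validation procedure.

    ``TS`` uses parameterization-test-set residuals, ``CV`` uses
    double-loop cross-validation residuals; either way the estimator
    simply stores the RMSE.
    """
    if kind not in UNIFORM_TAGS:
        raise ValueError(f"kind must be one of {UNIFORM_TAGS}, got {kind!r}")
    pred = np.asarray(predictions, dtype=float)
    obs = np.asarray(observations, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predictions and observations must align")
    if pred.size == 0:
        raise ValueError("cannot compute an RMSE from zero residuals")
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    return ErrorEstimator(tag=kind, sigma_floor=sigma_floor, uniform_sigma=rmse)


def make_variable_estimator(
    tag: str,
    sigma_exp: float,
    sigma_floor: float | None = None,
    *,
    calibration: ErrorCalibration | None = None,
    k: int | None = None,
    scaler: DescriptorScaler | None = None,
    train_Z: np.ndarray | None = None,
    mahal: MahalanobisMetric | None = None,
    cv_table: CVPredictionTable | None = None,
    ensemble: BaggedEnsemble | None = None,
    error_model: FittedModel | None = None,
) -> ErrorEstimator:
    """Assemble a variable error estimator, validating its components."""
    if tag not in VARIABLE_TAGS:
        raise ValueError(f"tag must be one of {VARIABLE_TAGS}, got {tag!r}")
    if sigma_floor is None:
        sigma_floor = sigma_exp
    metric = "mahalanobis" if tag.endswith("-MD") else "euclidean"
    needs_neighbors = tag.startswith(("D2M", "LE"))
    if needs_neighbors:
        if train_Z is None or k is None:
            raise ValueError(f"{tag} requires train_Z and k")
        if metric == "mahalanobis" and mahal is None:
            mahal = MahalanobisMetric(train_Z)
    if tag in CALIBRATED_TAGS and calibration is None:
        raise ValueError(f"{tag} requires a fitted ErrorCalibration")
    if tag.startswith("LE") and cv_table is None:
        raise ValueError(f"{tag} requires a CVPredictionTable")
    if tag in ("BV", "BVC") and ensemble is None:
        raise ValueError(f"{tag} requires a BaggedEnsemble")
    if tag == "EM" and error_model is None:
        raise ValueError("EM requires a fitted error model")
    return ErrorEstimator(
        tag=tag,
        sigma_floor=sigma_floor,
        calibration=calibration,
        k=k,
        metric=metric,
        scaler=scaler,
        train_Z=train_Z,
        mahal=mahal,
        cv_table=cv_table,
        ensemble=ensemble,
        error_model=error_model,
    )


def _parameterization_mean_kl(
    estimator: ErrorEstimator,
    X_param: np.ndarray,
    mu_pred: np.ndarray,
    obs: Sequence[GaussianDist],
) -> float:
    sigmas = estimator.predict_sigma(X_param)
    predicted = [GaussianDist(m, s) for m, s in zip(mu_pred, sigmas)]
    return mean_kl(DistributionPairSet(obs, predicted))


def optimize_k(
    candidate_ks: Sequence[int],
    method: str,
    *,
    X_param: np.ndarray,
    mu_pred: Sequence[float],
    observed: Sequence[GaussianDist],
    sigma_exp: float,
    scaler: DescriptorScaler,
    train_Z: np.ndarray,
    cv_table: CVPredictionTable | None = None,
    sigma_floor: float | None = None,
) -> int:
    """Pick the neighbour count minimising mean KL on the parameterization set.

    For calibrated methods (D2M, LEC) the error regression is refitted
    for every candidate k; ties go to the smallest k.  Candidates larger
    than the training set are dropped.
    """
    if method not in VARIABLE_TAGS or method in ("BV", "BVC", "EM"):
        raise ValueError(f"k optimisation applies to D2M/LE/LEC methods, not {method!r}")
    n_train = train_Z.shape[0]
    ks = sorted({int(k) for k in candidate_ks if 1 <= int(k) <= n_train})
    if not ks:
        raise ValueError("no candidate k fits the training-set size")
    mu_pred = np.asarray(mu_pred, dtype=float)
    obs_mu = np.array([o.mu for o in observed])
    residuals = obs_mu - mu_pred
    mahal = MahalanobisMetric(train_Z) if method.endswith("-MD") else None
    metric_obj = mahal if mahal is not None else "euclidean"
    Z_param = scaler.transform(np.atleast_2d(np.asarray(X_param, dtype=float)))
    if method.startswith(("LE", "LEC")) and cv_table is None:
        raise ValueError(f"{method} requires a CVPredictionTable")
    best_k, best_kl = None, np.inf
    for k in ks:
        if method.startswith("D2M"):
            scores = np.asarray(knn_mean_distance(Z_param, train_Z, k, metric_obj))
        else:  # LE-* / LEC-*
            scores = np.asarray(local_error(Z_param, train_Z, cv_table, k, metric_obj))
        if method in CALIBRATED_TAGS:
            cal = fit_error_regression(scores, residuals, sigma_exp, k=k)
            est = make_variable_estimator(
                method, sigma_exp, sigma_floor, calibration=cal, k=k,
                scaler=scaler, train_Z=train_Z, mahal=mahal, cv_table=cv_table,
            )
        else:
            est = make_variable_estimator(
                method, sigma_exp, sigma_floor, k=k,
                scaler=scaler, train_Z=train_Z, mahal=mahal, cv_table=cv_table,
            )
        kl = _parameterization_mean_kl(est, X_param, mu_pred, observed)
        if kl < best_kl - 1e-15:
            best_k, best_kl = k, kl
    return int(best_k)
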