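"""Predictive-distribution methods: model + error estimator.

A PD method pairs a fitted point-prediction model (which supplies
mu_pred) with a fitted error estimator (which supplies sigma_pred,
floored at the assay's experimental error) and emits Gaussian
predictive distributions N(mu_pred, sigma_pred).  Methods are labelled
"{ALGORITHM}:{ERRORMETHOD}", e.g. ``SVM:D2M-EUC`` or ``RF:BV``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distributions import GaussianDist
from .error_estimation import ErrorEstimator
from .models import FittedModel


@dataclass
class PDMethod:
    model: FittedModel
    estimator: ErrorEstimator
    sigma_floor: float
    algorithm_label: str = ""

    @property
    def label(self) -> str:
        alg = self.algorithm_label or self.model.spec.algorithm.upper()
        return f"{alg}:{self.estimator.tag}"

    def predict_distribution(self, x: np.ndarray) -> GaussianDist:
        """Predictive distribution for a single descriptor vector."""
        dists = self.predict_distributions(np.atleast_2d(np.asarray(x, dtype=float)))
        return dists[0]

    def predict_distributions(self, X: np.ndarray) -> list[GaussianDist]:
        """Batch prediction; output order matches input order."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        mu = self.model.predict(X)
        sigma = np.maximum(self.estimator.predict_sigma(X), self.sigma_floor)
        return [GaussianDist(float(m), float(s)) for m, s in zip(mu, sigma)]

    def prediction_frame(
        self, X: np.ndarray, compound_ids=None
    ) -> pd.DataFrame:
        """Predictions as a table: compound_id, mu_pred, sigma_pred, method."""
        dists = self.predict_distributions(X)
        if compound_ids is None:
            compound_ids = np.arange(len(dists))
        return pd.DataFrame(
            {
                "compound_id": list(compound_ids),
                "mu_pred": [d.mu for d in dists],
                "sigma_pred": [d.sigma for d in dists],
                "method": self.label,
            }
        )


def normalized_error(obs: GaussianDist, pred: GaussianDist) -> float:
    """(mu_obs - mu_pred) / sigma_pred: the residual in estimated-error units.

    If the predictive distributions are well specified, these scores are
    approximately standard normal over a test set.
    """
    return (obs.mu - pred.mu) / pred.sigma


def normalized_errors(
    obs_mu: np.ndarray, pred_mu: np.ndarray, pred_sigma: np.ndarray
) -> np.ndarray:
    """Vectorised :func:`normalized_error`."""
    obs_mu = np.asarray(obs_mu, dtype=float)
    pred_mu = np.asarray(pred_mu, dtype=float)
    pred_sigma = np.asarray(pred_sigma, dtype=float)
    if np.any(pred_sigma <= 0):
        raise ValueError("pred_sigma must be strictly positive")
    return (obs_mu - pred_mu) / pred_sigma
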