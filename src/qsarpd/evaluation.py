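"""Diagnostics for sets of predictive distributions.

Three complementary views of prediction-error quality:

* binned estimated-vs-observed RMSE — rank predictions by sigma_pred,
  bin, and compare each bin's estimated RMSE (root-mean-square of the
  sigmas) with the observed residual RMSE, with 95% Faber confidence
  intervals on the observed RMSE;
* KL-difference profiles — per-bin mean KL of a variable error method
  minus the equivalent uniform TS method; negative differences mean the
  variable method gained information in that bin;
* normalized-error normality — a one-sample Kolmogorov-Smirnov test of
  (mu_obs - mu_pred)/sigma_pred against the standard normal, plus
  histogram data with the unit-Gaussian overlay.

Faber's distribution-based approximation gives the relative standard
error of an RMSE estimated from n residuals as sigma_RMSE / RMSE ≈
sqrt(1/(2n)); the 95% interval uses a 1.96 multiplier.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import kstest

from .distributions import GaussianDist, kl_gaussian
from .target_profile import _bin_edges

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ErrorBin:
    """One bin of predictions with similar estimated errors."""

    indices: np.ndarray  # positions into the original input arrays
    estimated_rmse: float  # sqrt(mean sigma_pred^2)
    observed_rmse: float
    ci_halfwidth: float  # Faber 95% half-width on the observed RMSE
    mean_kl: float

    @property
    def n(self) -> int:
        return int(self.indices.size)


def faber_rmse_ci(rmse: float, n: int) -> tuple[float, float]:
    """95% confidence interval for an RMSE from n residuals."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if rmse < 0:
        raise ValueError("rmse must be >= 0")
    half = 1.96 * rmse * math.sqrt(1.0 / (2.0 * n))
    return (max(rmse - half, 0.0), rmse + half)


def _rank_by_sigma(pred: Sequence[GaussianDist]) -> np.ndarray:
    sigmas = np.array([q.sigma for q in pred])
    return np.argsort(sigmas, kind="stable")


def bin_by_estimated_error(
    preds: Sequence[GaussianDist],
    obs: Sequence[GaussianDist],
    bin_size: int,
) -> list[ErrorBin]:
    """Bins of ascending sigma_pred; remainder merged into the last bin.

    Per bin: estimated RMSE aggregates the sigmas as a root-mean-square
    (an RMSE is an L2 object), observed RMSE comes from the residuals
    mu_obs - mu_pred, and the Faber interval is attached to the
    observed RMSE.
    """
    if len(preds) != len(obs):
        raise ValueError("preds and obs must align")
    n = len(preds)
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    if n < bin_size:
        logger.warning("n=%d < bin_size=%d; returning a single bin", n, bin_size)
    order = _rank_by_sigma(preds)
    sigmas = np.array([q.sigma for q in preds])[order]
    residuals = np.array([p.mu - q.mu for p, q in zip(obs, preds)])[order]
    kls = np.array([kl_gaussian(p, q) for p, q in zip(obs, preds)])[order]
    bins = []
    for lo, hi in _bin_edges(n, bin_size):
        idx = order[lo:hi]
        obs_rmse = float(np.sqrt(np.mean(residuals[lo:hi] ** 2)))
        half = 1.96 * obs_rmse * math.sqrt(1.0 / (2.0 * (hi - lo)))
        bins.append(
            ErrorBin(
                indices=idx,
                estimated_rmse=float(np.sqrt(np.mean(sigmas[lo:hi] ** 2))),
                observed_rmse=obs_rmse,
                ci_halfwidth=half,
                mean_kl=float(np.mean(kls[lo:hi])),
            )
        )
    return bins


def kl_difference_profile(
    variable_preds: Sequence[GaussianDist],
    uniform_preds: Sequence[GaussianDist],
    obs: Sequence[GaussianDist],
    bin_size: int,
) -> np.ndarray:
    """Per-bin mean KL of the variable method minus the uniform method.

    Binning follows the VARIABLE method's sigma_pred ranking, so the
    first bin holds the predictions claimed most reliable and the last
    bin the least.  A negative difference is an information gain over
    the uniform baseline in that bin.
    """
    if not (len(variable_preds) == len(uniform_preds) == len(obs)):
        raise ValueError("prediction sets and observations must align")
    n = len(obs)
    order = _rank_by_sigma(variable_preds)
    kl_var = np.array(
        [kl_gaussian(p, q) for p, q in zip(obs, variable_preds)]
    )[order]
    kl_uni = np.array(
        [kl_gaussian(p, q) for p, q in zip(obs, uniform_preds)]
    )[order]
    diffs = []
    for lo, hi in _bin_edges(n, bin_size):
        diffs.append(float(kl_var[lo:hi].mean() - kl_uni[lo:hi].mean()))
    return np.array(diffs)


def normality_diagnostics(normalized_errors: Sequence[float], n_hist_bins: int = 40) -> dict:
    """KS test of normalized errors against N(0,1), plus histogram data.

    Returns ``{"ks_statistic", "p_value", "histogram": (density, edges),
    "overlay": (x, pdf)}``.  A constant input is degenerate: the KS
    statistic then reflects the maximal CDF gap at that point.
    """
    z = np.asarray(normalized_errors, dtype=float)
    if z.size < 8:
        raise ValueError("need at least 8 normalized errors")
    stat, pval = kstest(z, "norm")
    density, edges = np.histogram(z, bins=n_hist_bins, density=True)
    span = max(abs(z.min()), abs(z.max()), 4.0)
    x = np.linspace(-span, span, 201)
    pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
    return {
        "ks_statistic": float(stat),
        "p_value": float(pval),
        "histogram": (density, edges),
        "overlay": (x, pdf),
    }
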