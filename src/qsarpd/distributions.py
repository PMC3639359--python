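"""Gaussian distributions and Kullback-Leibler divergence.

Both experimental measurements and model predictions are represented as
Gaussians.  The KL divergence of a predictive distribution Q from the
measurement ("true") distribution P,

    D_KL(P || Q) = ln(sigma_q / sigma_p)
                   + (sigma_p^2 + (mu_p - mu_q)^2) / (2 sigma_q^2)
                   - 1/2,

is minimised when the prediction mean and error both match the
measurement's.  The mean divergence over a test set is the model-selection
criterion: lower mean KL means more informative predictive distributions.

Because a prediction cannot be more precise than the measurement it is
compared with, predictive sigmas are floored at the assay's experimental
error before scoring (``apply_sigma_floor``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np


class InvalidDistributionError(ValueError):
    """Raised for a Gaussian with non-positive sigma or non-finite mean."""


@dataclass(frozen=True)
class GaussianDist:
    """A Gaussian N(mu, sigma) in the property's units (e.g. log units)."""

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise InvalidDistributionError(f"mu must be finite, got {self.mu}")
        if not (self.sigma > 0) or not math.isfinite(self.sigma):
            raise InvalidDistributionError(
                f"sigma must be strictly positive and finite, got {self.sigma}"
            )

    def pdf(self, x: np.ndarray) -> np.ndarray:
        z = (np.asarray(x, dtype=float) - self.mu) / self.sigma
        return np.exp(-0.5 * z * z) / (self.sigma * math.sqrt(2.0 * math.pi))


@dataclass(frozen=True)
class DistributionPairSet:
    """Index-aligned observed (S_P) and predicted (S_Q) distributions."""

    observed: tuple[GaussianDist, ...]
    predicted: tuple[GaussianDist, ...]

    def __init__(
        self,
        observed: Iterable[GaussianDist],
        predicted: Iterable[GaussianDist],
    ) -> None:
        obs = tuple(observed)
        pred = tuple(predicted)
        if len(obs) != len(pred):
            raise ValueError(
                f"observed and predicted lengths differ: {len(obs)} != {len(pred)}"
            )
        if len(obs) == 0:
            raise ValueError("DistributionPairSet must contain at least one pair")
        object.__setattr__(self, "observed", obs)
        object.__setattr__(self, "predicted", pred)

    def __len__(self) -> int:
        return len(self.observed)


def kl_gaussian(p: GaussianDist, q: GaussianDist) -> float:
    """KL divergence D_KL(P || Q) between two Gaussians, closed form.

    Nonnegative; zero iff P == Q.  P is the true (measurement)
    distribution, Q the model (predictive) distribution.
    """
    var_q = q.sigma * q.sigma
    return (
        math.log(q.sigma / p.sigma)
        + (p.sigma * p.sigma + (p.mu - q.mu) ** 2) / (2.0 * var_q)
        - 0.5
    )


def kl_numeric_oracle(
    p: GaussianDist,
    q: GaussianDist,
    grid_halfwidth_sd: float = 12.0,
    n_points: int = 100_001,
) -> float:
    """Trapezoid quadrature of the defining integral ∫ p ln(p/q) dx.

    The grid spans ``grid_halfwidth_sd`` combined standard deviations
    around both means, wide enough that truncation error is negligible
    for the default 12-sigma window.  Used as an independent check of
    :func:`kl_gaussian`; slow by construction.
    """
    if n_points < 1000:
        raise ValueError("n_points must be >= 1000 for a trustworthy quadrature")
    spread = p.sigma + q.sigma
    lo = min(p.mu, q.mu) - grid_halfwidth_sd * spread
    hi = max(p.mu, q.mu) + grid_halfwidth_sd * spread
    x = np.linspace(lo, hi, n_points)
    px = p.pdf(x)
    # ln(p/q) expanded analytically to avoid overflow in the densities' ratio
    log_ratio = (
        np.log(q.sigma / p.sigma)
        - 0.5 * ((x - p.mu) / p.sigma) ** 2
        + 0.5 * ((x - q.mu) / q.sigma) ** 2
    )
    return float(np.trapezoid(px * log_ratio, x))


def mean_kl(pairs: DistributionPairSet) -> float:
    """Mean KL divergence over a set of (observed, predicted) pairs.

    The mean of the per-compound divergences measures the total entropy
    (inverse information) of a set of predictive distributions; the PD
    method with the lowest mean KL is preferred.
    """
    return float(
        np.mean([kl_gaussian(p, q) for p, q in zip(pairs.observed, pairs.predicted)])
    )


def kl_per_pair(pairs: DistributionPairSet) -> np.ndarray:
    """Per-compound KL divergences, in input order."""
    return np.array(
        [kl_gaussian(p, q) for p, q in zip(pairs.observed, pairs.predicted)]
    )


def apply_sigma_floor(sigma_pred: float, sigma_floor: float) -> float:
    """Floor an estimated prediction error at the experimental error.

    An error-estimation method that claims a prediction error below the
    assay's single-shot experimental error is re-assigned the
    experimental error: a model cannot predict an experimental result
    more precisely than the measurement itself.
    """
    if sigma_floor <= 0:
        raise ValueError(f"sigma_floor must be > 0, got {sigma_floor}")
    if sigma_pred < 0:
        raise ValueError(f"sigma_pred must be >= 0, got {sigma_pred}")
    return max(sigma_pred, sigma_floor)


def floor_sigmas(sigma_pred: Sequence[float] | np.ndarray, sigma_floor: float) -> np.ndarray:
    """Vectorised :func:`apply_sigma_floor`."""
    if sigma_floor <= 0:
        raise ValueError(f"sigma_floor must be > 0, got {sigma_floor}")
    arr = np.asarray(sigma_pred, dtype=float)
    if np.any(arr < 0):
        raise ValueError("sigma_pred values must be >= 0")
    return np.maximum(arr, sigma_floor)
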