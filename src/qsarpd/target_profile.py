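"""Probabilities of hitting target property profiles.

A target profile is one or more property intervals a compound should
satisfy (e.g. LogD in 2.5-3.5, or Caco2 permeability > -5 log cm/s).
The probability that a compound hits a single interval is the mass of
its Gaussian predictive distribution inside the interval, computed with
the normal CDF; for multi-objective profiles the per-endpoint
probabilities are multiplied, assuming independence of the endpoint
predictions.

``probability_calibration`` checks such probabilities against observed
outcomes by ranking compounds by estimated probability, binning, and
comparing each bin's mean estimated probability with its observed hit
fraction (with 95% central-limit-theorem error bars, reported as valid
only when the bin contains more than 5 hits).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .distributions import GaussianDist


@dataclass(frozen=True)
class ProfileComponent:
    endpoint: str
    lower: float  # -inf allowed
    upper: float  # +inf allowed

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(
                f"profile component needs lower < upper, got [{self.lower}, {self.upper}]"
            )


@dataclass(frozen=True)
class TargetProfile:
    components: tuple[ProfileComponent, ...]

    def __init__(self, components: Iterable[ProfileComponent | tuple]):
        comps = tuple(
            c if isinstance(c, ProfileComponent) else ProfileComponent(*c)
            for c in components
        )
        if not comps:
            raise ValueError("a target profile needs at least one component")
        object.__setattr__(self, "components", comps)

    def __len__(self) -> int:
        return len(self.components)


def hit_probability(pred: GaussianDist, lower: float, upper: float) -> float:
    """P(lower <= X <= upper) for X ~ N(mu_pred, sigma_pred)."""
    if not lower < upper:
        raise ValueError(f"need lower < upper, got [{lower}, {upper}]")
    hi = 1.0 if math.isinf(upper) and upper > 0 else norm.cdf(upper, pred.mu, pred.sigma)
    lo = 0.0 if math.isinf(lower) and lower < 0 else norm.cdf(lower, pred.mu, pred.sigma)
    return float(hi - lo)


def multi_objective_probability(
    preds: Sequence[GaussianDist], profile: TargetProfile
) -> float:
    """Product of per-endpoint hit probabilities (independent endpoints)."""
    if len(preds) != len(profile):
        raise ValueError(
            f"got {len(preds)} predictions for a {len(profile)}-component profile"
        )
    p = 1.0
    for pred, comp in zip(preds, profile.components):
        p *= hit_probability(pred, comp.lower, comp.upper)
    return p


def probability_calibration(
    probabilities: Sequence[float],
    hits: Sequence[bool],
    bin_size: int,
) -> pd.DataFrame:
    """Binned calibration table for estimated hit probabilities.

    Compounds are ranked ascending by estimated probability and grouped
    into bins of ``bin_size``; a final partial bin is merged into the
    preceding one.  Returns one row per bin with the mean estimated
    probability, the observed hit fraction, the 95% CLT half-width on
    that fraction, and an ``interval_valid`` flag (bin hit count > 5,
    where the normal approximation is reasonable).  The frame carries
    the overall hit rate in ``df.attrs["overall_hit_rate"]``.
    """
    p = np.asarray(probabilities, dtype=float)
    h = np.asarray(hits, dtype=bool)
    if p.shape != h.shape:
        raise ValueError("probabilities and hits must have equal length")
    if p.size == 0:
        raise ValueError("empty input")
    if bin_size < 2:
        raise ValueError("bin_size must be >= 2")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    p, h = p[order], h[order]
    edges = _bin_edges(p.size, bin_size)
    rows = []
    for lo, hi in edges:
        pb, hb = p[lo:hi], h[lo:hi]
        n = hb.size
        frac = float(hb.mean())
        half = 1.96 * math.sqrt(frac * (1.0 - frac) / n)
        rows.append(
            {
                "n": n,
                "n_hits": int(hb.sum()),
                "mean_probability": float(pb.mean()),
                "observed_fraction": frac,
                "ci95_halfwidth": half,
                "interval_valid": bool(hb.sum() > 5),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["overall_hit_rate"] = float(h.mean())
    df.attrs["n_total"] = int(h.size)
    df.attrs["n_hits_total"] = int(h.sum())
    return df


def _bin_edges(n: int, bin_size: int) -> list[tuple[int, int]]:
    """Full bins of ``bin_size``; the remainder is merged into the last bin."""
    n_full = n // bin_size
    if n_full == 0:
        return [(0, n)]
    edges = [(i * bin_size, (i + 1) * bin_size) for i in range(n_full)]
    lo, _ = edges[-1]
    edges[-1] = (lo, n)
    return edges
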