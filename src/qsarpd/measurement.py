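"""Experimental error from QC replicates and measurement distributions.

Assays carry a single-shot measurement error ``sigma_exp``, estimated by
pooling the within-compound deviations of quality-control (QC) compounds
that are run through the assay repeatedly:

    sigma_exp = sqrt( (1 / sum_i N_i) * sum_i sum_j (QC_ij - mean_i)^2 )

Pooling is maximum-likelihood (denominator is the total measurement
count, with no degrees-of-freedom correction), so the estimate has a
small negative bias for small replicate counts.  A compound measured N
times has an error on its mean of

    sigma_obs = sigma_exp / sqrt(N).

All non-QC compounds are assumed to share the QC-derived sigma_exp.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class QCSet:
    """Replicate measurements for one quality-control compound."""

    compound_id: str
    values: tuple[float, ...]

    def __init__(self, compound_id: str, values: Iterable[float]) -> None:
        object.__setattr__(self, "compound_id", str(compound_id))
        object.__setattr__(self, "values", tuple(float(v) for v in values))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class MeasurementDistribution:
    """N(mu_obs, sigma_obs) for one compound; mu_obs is the replicate mean."""

    compound_id: str
    mu_obs: float
    sigma_obs: float
    n_measurements: int


def experimental_error_from_qc(qc_sets: Sequence[QCSet]) -> float:
    """Pooled single-shot assay error from QC replicate sets.

    Singleton QC sets carry no variance information and would only
    inflate the denominator, so they are excluded (with a warning).
    Raises if no QC set has at least two measurements.
    """
    usable = [s for s in qc_sets if len(s) >= 2]
    n_dropped = len(qc_sets) - len(usable)
    if n_dropped:
        logger.warning("excluding %d singleton QC set(s) from pooling", n_dropped)
    if not usable:
        raise ValueError(
            "need at least one QC compound with >= 2 measurements to pool"
        )
    total_n = 0
    ss = 0.0
    for s in usable:
        v = np.asarray(s.values, dtype=float)
        ss += float(np.sum((v - v.mean()) ** 2))
        total_n += len(v)
    return math.sqrt(ss / total_n)


def sigma_obs(sigma_exp: float, n_measurements: int) -> float:
    """Error on a compound's mean of ``n_measurements`` replicates."""
    if sigma_exp <= 0:
        raise ValueError(f"sigma_exp must be > 0, got {sigma_exp}")
    if n_measurements < 1:
        raise ValueError(f"n_measurements must be >= 1, got {n_measurements}")
    return sigma_exp / math.sqrt(n_measurements)


def build_measurement_distributions(
    records: pd.DataFrame | Mapping[str, Sequence[float]],
    sigma_exp: float,
) -> list[MeasurementDistribution]:
    """One measurement distribution per compound from a replicate table.

    ``records`` is either a DataFrame with columns ``compound_id`` and
    ``value`` (one row per replicate) or a mapping compound_id ->
    replicate values.  Compounds without any finite value are skipped
    with a logged warning.
    """
    if isinstance(records, pd.DataFrame):
        grouped: Mapping[str, Sequence[float]] = {
            str(cid): grp["value"].to_numpy(dtype=float)
            for cid, grp in records.groupby("compound_id", sort=False)
        }
    else:
        grouped = records

    out: list[MeasurementDistribution] = []
    for cid, values in grouped.items():
        v = np.asarray(list(values), dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            logger.warning("compound %s has no usable values; skipped", cid)
            continue
        out.append(
            MeasurementDistribution(
                compound_id=str(cid),
                mu_obs=float(v.mean()),
                sigma_obs=sigma_obs(sigma_exp, v.size),
                n_measurements=int(v.size),
            )
        )
    return out
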