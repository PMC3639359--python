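"""Synthetic compound series with the structure the framework assumes.

Industrial property datasets are temporally ordered explorations of
chemical space: new compounds drift away from the space the model was
trained on, and prediction difficulty grows with that distance.  The
generator emulates exactly this:

* descriptors for month m are drawn from N(m * drift * u, I) for a fixed
  unit direction u, so the compound cloud moves steadily;
* each compound's true value is a latent function of its descriptors
  (linear, with an optional smooth tanh nonlinearity) plus a
  "model-difficulty" deviation whose variance grows linearly with the
  Euclidean distance d from the initial-month centroid:
  Var[deviation] = noise_slope * d.  A model that learns the latent
  function perfectly therefore has residual variance
  noise_slope * d + sigma_exp^2 against single-shot measurements — a
  distance-to-model error structure by construction;
* measurements add i.i.d. Gaussian single-shot noise N(0, sigma_exp),
  with a configurable fraction of compounds measured in replicate;
* QC compounds are re-measured many times to allow pooled estimation of
  sigma_exp.

What this does NOT emulate: real molecular descriptors (dimension
defaults to 20, not the hundreds used in production), assay drift,
non-Gaussian error tails, or activity cliffs.  Passing tests on this
fixture show the machinery is correct under its own assumptions, not
that those assumptions hold for any particular assay.

A ground-truth sidecar records the latent values, difficulty deviations
and distances so oracle tests can check parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .distributions import GaussianDist, DistributionPairSet


@dataclass(frozen=True)
class SyntheticConfig:
    n_per_month: int = 150
    n_months: int = 18
    n_descriptors: int = 20
    drift: float = 0.25  # descriptor-SD units per month
    coef_scale: float = 1.0  # SD of the latent linear response
    nonlinearity: float = 0.0  # amplitude of the optional tanh component
    noise_slope: float = 0.037  # difficulty variance per unit distance
    sigma_exp: float = 0.2  # single-shot measurement error (log units)
    replicate_prob: float = 0.2
    max_replicates: int = 3
    qualified_prob: float = 0.02  # fraction reported as "<x" / ">x"
    n_qc_compounds: int = 5
    qc_replicates: int = 200
    start_month: str = "2010-01"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma_exp <= 0:
            raise ValueError("sigma_exp must be > 0")
        if self.drift < 0:
            raise ValueError("drift must be >= 0")
        if self.noise_slope < 0:
            raise ValueError("noise_slope must be >= 0")
        if self.n_per_month < 1 or self.n_months < 1 or self.n_descriptors < 1:
            raise ValueError("counts must be >= 1")


@dataclass
class SyntheticDataset:
    measurements: pd.DataFrame  # compound_id, date, value (str), excluded
    descriptors: pd.DataFrame  # compound_id + descriptor columns
    qc: pd.DataFrame  # compound_id, value
    sidecar: dict = field(repr=False, default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.measurements.to_csv(outdir / "measurements.csv", index=False)
        self.descriptors.to_csv(outdir / "descriptors.csv", index=False)
        self.qc.to_csv(outdir / "qc.csv", index=False)
        sidecar = dict(self.sidecar)
        sidecar_json = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in sidecar.items()
        }
        (outdir / "sidecar.json").write_text(json.dumps(sidecar_json, indent=1))


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate one temporally ordered synthetic dataset."""
    rng = np.random.default_rng(config.seed)
    d = config.n_descriptors
    u = rng.normal(size=d)
    u /= np.linalg.norm(u)
    beta = rng.normal(scale=config.coef_scale / np.sqrt(d), size=d)
    beta2 = rng.normal(scale=1.0 / np.sqrt(d), size=d)

    n_total = config.n_per_month * config.n_months
    months = np.repeat(np.arange(config.n_months), config.n_per_month)
    X = rng.normal(size=(n_total, d)) + months[:, None] * config.drift * u[None, :]

    # difficulty grows with distance from where the initial model lives
    centroid = X[months == 0].mean(axis=0)
    dist = np.linalg.norm(X - centroid, axis=1)
    latent = X @ beta + config.nonlinearity * np.tanh(X @ beta2)
    eps_model = rng.normal(size=n_total) * np.sqrt(config.noise_slope * dist)
    true_value = latent + eps_model

    ids = np.array([f"CPD{i:06d}" for i in range(n_total)])
    start = pd.Period(config.start_month, freq="M")
    days = rng.integers(1, 29, size=n_total)

    rep_draw = rng.random(n_total)
    n_reps = np.where(
        rep_draw < config.replicate_prob,
        rng.integers(2, config.max_replicates + 1, size=n_total),
        1,
    )
    qual_draw = rng.random(n_total)

    rows = []
    for i in range(n_total):
        date = (start + int(months[i])).to_timestamp() + pd.Timedelta(
            days=int(days[i]) - 1
        )
        date_str = date.strftime("%Y-%m-%d")
        for _ in range(int(n_reps[i])):
            v = true_value[i] + rng.normal(scale=config.sigma_exp)
            if qual_draw[i] < config.qualified_prob:
                qual = ">" if v >= latent.mean() else "<"
                value = f"{qual}{v:.4f}"
            else:
                value = f"{v:.4f}"
            rows.append((ids[i], date_str, value, 0))
    measurements = pd.DataFrame(
        rows, columns=["compound_id", "date", "value", "excluded"]
    )

    descriptors = pd.DataFrame(X, columns=[f"x{j:03d}" for j in range(d)])
    descriptors.insert(0, "compound_id", ids)

    qc_means = rng.normal(scale=1.0, size=config.n_qc_compounds)
    qc_rows = []
    for q in range(config.n_qc_compounds):
        vals = qc_means[q] + rng.normal(
            scale=config.sigma_exp, size=config.qc_replicates
        )
        for v in vals:
            qc_rows.append((f"QC{q:02d}", float(v)))
    qc = pd.DataFrame(qc_rows, columns=["compound_id", "value"])

    sidecar = {
        "config": asdict(config),
        "compound_id": ids,
        "month": months,
        "latent": latent,
        "eps_model": eps_model,
        "true_value": true_value,
        "distance_to_initial_centroid": dist,
        "n_replicates": n_reps,
        "centroid": centroid,
    }
    return SyntheticDataset(measurements, descriptors, qc, sidecar)


def make_worked_example() -> DistributionPairSet:
    """The single-compound worked example: one measurement, three models.

    The measurement distribution P = N(0, 1) is compared with three
    candidate predictive distributions Q1 = N(2.5, 1.5), Q2 = N(2.0,
    1.5) and Q3 = N(2.5, 3.0).  Q2 is the most accurate point
    prediction (residual 2.0 vs 2.5) but claims an error too small to
    cover the truth; the wide Q3 carries the lowest KL divergence.
    """
    p = GaussianDist(0.0, 1.0)
    q1 = GaussianDist(2.5, 1.5)
    q2 = GaussianDist(2.0, 1.5)
    q3 = GaussianDist(2.5, 3.0)
    return DistributionPairSet(observed=[p, p, p], predicted=[q1, q2, q3])
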