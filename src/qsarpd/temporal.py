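"""Temporal validation harness: growing-window monthly retraining.

The experimental protocol mirrors how property models are used in
practice.  The data are split chronologically into

* an initial training set (everything before ``train_end``),
* a parameterization test set (``train_end`` to ``param_end``), used
  once to fit the error-estimation parameters (m, c, k, uniform RMSEs),
  which are then frozen,
* consecutive monthly experimental test sets from ``param_end`` onward.

For each month, the models are rebuilt on all data collected before
that month (with the training set reduced to a cap of the most recent
compounds plus a random sample of the remainder), the month's compounds
are predicted with every configured PD method, and the monthly
predictions are pooled for evaluation.  Error-calibration parameters
are never refitted after the parameterization pass.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .distributions import DistributionPairSet, GaussianDist, mean_kl
from .error_estimation import (
    DEFAULT_K_GRID,
    CALIBRATED_TAGS,
    UNIFORM_TAGS,
    VARIABLE_TAGS,
    ErrorEstimator,
    MahalanobisMetric,
    fit_error_regression,
    knn_mean_distance,
    local_error,
    make_variable_estimator,
    optimize_k,
)
from .measurement import sigma_obs as _sigma_obs
from .models import (
    DescriptorScaler,
    RegressorSpec,
    double_loop_cv,
    fit,
    fit_bagged,
    make_spec,
)

logger = logging.getLogger(__name__)

_QUALIFIED_RE = re.compile(
    r"^\s*(?P<qual><=|>=|<|>)?\s*(?P<num>[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?)\s*$"
)


def parse_qualified_value(raw: str) -> tuple[float, str | None]:
    """Parse a possibly qualified measurement string.

    Qualified data points (">5", "<-1.4") are treated as quantitative
    measurements: the numeral is returned with the qualifying symbol
    stripped but retained as metadata.  Raises ValueError for anything
    unparseable.
    """
    m = _QUALIFIED_RE.match(str(raw))
    if m is None:
        raise ValueError(f"unparseable measurement value: {raw!r}")
    return float(m.group("num")), m.group("qual")


def reduce_training_set(
    records: pd.DataFrame,
    cap: int = 35_000,
    recent: int = 20_000,
    random_n: int = 15_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Cap a training set at the most recent compounds plus a random sample.

    If the set holds more than ``cap`` compounds, keep exactly the
    ``recent`` most recent ones and a seeded without-replacement sample
    of ``random_n`` from the remainder.
    """
    if cap < recent + random_n:
        raise ValueError("cap must be >= recent + random_n")
    if len(records) <= cap:
        return records
    order = records["date"].to_numpy().argsort(kind="stable")
    recent_pos = order[-recent:]
    remainder_pos = order[:-recent]
    rng = np.random.default_rng(seed)
    sampled = rng.choice(remainder_pos, size=random_n, replace=False)
    keep = np.sort(np.concatenate([recent_pos, sampled]))
    return records.iloc[keep]


def prepare_compound_table(
    measurements: pd.DataFrame, sigma_exp: float
) -> pd.DataFrame:
    """Collapse a replicate-level measurement table to one row per compound.

    Parses qualified values, drops rows flagged ``excluded`` and rows
    whose value cannot be parsed (logged), and attaches mu_obs (mean of
    replicates), sigma_obs (sigma_exp / sqrt(n)), and the first
    measurement date as the compound's timestamp.
    """
    df = measurements.copy()
    if "excluded" in df.columns:
        n_exc = int((df["excluded"].astype(int) != 0).sum())
        if n_exc:
            logger.info("dropping %d excluded measurement rows", n_exc)
        df = df[df["excluded"].astype(int) == 0]
    values = []
    keep_rows = []
    for idx, raw in df["value"].items():
        try:
            v, _ = parse_qualified_value(raw)
        except ValueError:
            logger.warning("dropping unparseable measurement row %r: %r", idx, raw)
            continue
        values.append(v)
        keep_rows.append(idx)
    df = df.loc[keep_rows].copy()
    df["value_num"] = values
    df["date"] = pd.to_datetime(df["date"])
    grouped = df.groupby("compound_id", sort=False).agg(
        mu_obs=("value_num", "mean"),
        n_measurements=("value_num", "size"),
        date=("date", "min"),
    )
    grouped["sigma_obs"] = [
        _sigma_obs(sigma_exp, int(n)) for n in grouped["n_measurements"]
    ]
    return grouped.reset_index()


def combined_test_set_size(monthly_counts: Sequence[int] | dict) -> int:
    """Total compounds pooled over the monthly experimental test sets.

    Accepts either a sequence of per-month compound counts or a mapping
    month -> count, mirroring the bookkeeping of the combined test set
    used for final evaluation.
    """
    counts = (
        list(monthly_counts.values())
        if isinstance(monthly_counts, dict)
        else list(monthly_counts)
    )
    if any(int(c) < 0 for c in counts):
        raise ValueError("monthly counts must be nonnegative")
    return int(sum(int(c) for c in counts))


@dataclass(frozen=True)
class TemporalSplit:
    """Chronological split into training / parameterization / monthly tests."""

    train_end: pd.Timestamp
    param_end: pd.Timestamp
    month_starts: tuple[pd.Timestamp, ...]

    @classmethod
    def from_dates(
        cls, dates: pd.Series, train_end, param_end
    ) -> "TemporalSplit":
        train_end = pd.Timestamp(train_end)
        param_end = pd.Timestamp(param_end)
        if not train_end < param_end:
            raise ValueError("train_end must precede param_end")
        last = pd.Timestamp(pd.to_datetime(dates).max())
        starts = []
        cur = param_end
        while cur <= last:
            starts.append(cur)
            cur = (cur.to_period("M") + 1).to_timestamp()
        return cls(train_end, param_end, tuple(starts))


@dataclass
class GrowingWindowResult:
    predictions: pd.DataFrame  # compound_id, month, method, mu_pred, sigma_pred, ...
    pairs: dict[str, DistributionPairSet]
    mean_kl: dict[str, float]
    estimator_states: dict[str, dict]
    months: list[str]
    uniform_rmse: dict[str, float] = field(default_factory=dict)


def _needs_cv(methods: Sequence[str]) -> bool:
    return any(t == "CV" or t.startswith(("LE", "LEC")) or t == "EM" for t in methods)


def _needs_ensemble(methods: Sequence[str]) -> bool:
    return any(t in ("BV", "BVC") for t in methods)


def run_growing_window(
    measurements: pd.DataFrame,
    descriptors: pd.DataFrame,
    *,
    sigma_exp: float,
    train_end,
    param_end,
    algorithm: str = "ridge",
    error_methods: Sequence[str] = ("TS", "CV", "D2M-EUC"),
    spec: RegressorSpec | None = None,
    seed: int = 0,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    outer_folds: int = 5,
    inner_folds: int = 5,
    n_members: int = 25,
    cap: int = 35_000,
    recent: int = 20_000,
    random_n: int = 15_000,
) -> GrowingWindowResult:
    """Run the full temporal protocol and pool monthly predictions.

    Error-estimation parameters are fitted once on the parameterization
    test set with the initial model, then frozen; the point-prediction
    model (and any training-set-dependent estimator components: scaled
    descriptors, CV residual tables, bagged ensembles, the error model)
    is rebuilt for every monthly window on all data preceding it.
    """
    for tag in error_methods:
        if tag not in UNIFORM_TAGS + VARIABLE_TAGS:
            raise ValueError(f"unknown error method {tag!r}")
    if spec is None:
        spec = make_spec(algorithm)
    alg_label = (spec.algorithm or algorithm).upper()

    table = prepare_compound_table(measurements, sigma_exp)
    desc_cols = [c for c in descriptors.columns if c != "compound_id"]
    table = table.merge(descriptors, on="compound_id", how="inner")
    split = TemporalSplit.from_dates(table["date"], train_end, param_end)

    def xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        return df[desc_cols].to_numpy(dtype=float), df["mu_obs"].to_numpy(dtype=float)

    # ---- parameterization pass -------------------------------------------
    train0 = table[table["date"] < split.train_end]
    param = table[(table["date"] >= split.train_end) & (table["date"] < split.param_end)]
    if len(train0) < 10 or len(param) < 10:
        raise ValueError("initial training and parameterization sets are too small")
    train0 = reduce_training_set(train0, cap, recent, random_n, seed=seed)
    X0, y0 = xy(train0)
    scaler0 = DescriptorScaler().fit(X0)
    Z0 = scaler0.transform(X0)
    model0 = fit(spec, Z0, y0, seed=seed)

    Xp, yp = xy(param)
    Zp = scaler0.transform(Xp)
    mu_param = model0.predict(Zp)
    obs_param = [
        GaussianDist(m, s) for m, s in zip(param["mu_obs"], param["sigma_obs"])
    ]
    resid_param = yp - mu_param

    cv0 = (
        double_loop_cv(spec, Z0, y0, outer_folds, inner_folds, seed=seed)
        if _needs_cv(error_methods)
        else None
    )
    ens0 = (
        fit_bagged(spec, Z0, y0, n_members=n_members, seed=seed)
        if _needs_ensemble(error_methods)
        else None
    )

    frozen: dict[str, dict] = {}
    for tag in error_methods:
        if tag == "TS":
            frozen[tag] = {"uniform_sigma": float(np.sqrt(np.mean(resid_param**2)))}
        elif tag == "CV":
            frozen[tag] = {"uniform_sigma": cv0.rmse()}
        elif tag in ("BV", "EM"):
            frozen[tag] = {}
        elif tag == "BVC":
            scores = ens0.spread(Zp)
            cal = fit_error_regression(scores, resid_param, sigma_exp)
            frozen[tag] = {"calibration": cal}
        else:  # D2M-* / LE-* / LEC-*
            best_k = optimize_k(
                k_grid,
                tag,
                X_param=Xp,
                mu_pred=mu_param,
                observed=obs_param,
                sigma_exp=sigma_exp,
                scaler=scaler0,
                train_Z=Z0,
                cv_table=cv0,
            )
            entry: dict = {"k": best_k}
            if tag in CALIBRATED_TAGS:
                mahal = MahalanobisMetric(Z0) if tag.endswith("-MD") else None
                metric_obj = mahal if mahal is not None else "euclidean"
                if tag.startswith("D2M"):
                    scores = np.asarray(
                        knn_mean_distance(Zp, Z0, best_k, metric_obj)
                    )
                else:
                    scores = np.asarray(
                        local_error(Zp, Z0, cv0, best_k, metric_obj)
                    )
                entry["calibration"] = fit_error_regression(
                    scores, resid_param, sigma_exp, k=best_k
                )
            frozen[tag] = entry

    # ---- monthly growing-window loop -------------------------------------
    rows = []
    obs_by_method: dict[str, list[GaussianDist]] = {t: [] for t in error_methods}
    pred_by_method: dict[str, list[GaussianDist]] = {t: [] for t in error_methods}
    months_used: list[str] = []

    for ms in split.month_starts:
        me = (ms.to_period("M") + 1).to_timestamp()
        test = table[(table["date"] >= ms) & (table["date"] < me)]
        if test.empty:
            logger.warning("month %s has no test compounds; skipped", ms.date())
            continue
        months_used.append(str(ms.to_period("M")))
        train = table[table["date"] < ms]
        train = reduce_training_set(train, cap, recent, random_n, seed=seed)
        Xt, yt = xy(train)
        scaler = DescriptorScaler().fit(Xt)
        Zt = scaler.transform(Xt)
        model = fit(spec, Zt, yt, seed=seed)
        cv = (
            double_loop_cv(spec, Zt, yt, outer_folds, inner_folds, seed=seed)
            if _needs_cv(error_methods)
            else None
        )
        ens = (
            fit_bagged(spec, Zt, yt, n_members=n_members, seed=seed)
            if _needs_ensemble(error_methods)
            else None
        )
        error_model = None
        if "EM" in error_methods:
            em_spec = make_spec("ridge")
            error_model = fit(em_spec, Zt, cv.abs_errors, seed=seed)

        Xm = test[desc_cols].to_numpy(dtype=float)
        Zm = scaler.transform(Xm)
        mu_m = model.predict(Zm)
        obs_m = [
            GaussianDist(m, s) for m, s in zip(test["mu_obs"], test["sigma_obs"])
        ]

        for tag in error_methods:
            fr = frozen[tag]
            if tag in UNIFORM_TAGS:
                est = ErrorEstimator(
                    tag=tag, sigma_floor=sigma_exp, uniform_sigma=fr["uniform_sigma"]
                )
            else:
                est = make_variable_estimator(
                    tag,
                    sigma_exp,
                    calibration=fr.get("calibration"),
                    k=fr.get("k"),
                    scaler=None,  # queries passed pre-scaled below
                    train_Z=Zt,
                    cv_table=cv,
                    ensemble=ens,
                    error_model=error_model,
                )
            sigmas = est.predict_sigma(Zm, n=len(test))
            label = f"{alg_label}:{tag}"
            for cid, mo, so, mp, sp in zip(
                test["compound_id"], test["mu_obs"], test["sigma_obs"], mu_m, sigmas
            ):
                rows.append(
                    {
                        "compound_id": cid,
                        "month": str(ms.to_period("M")),
                        "method": label,
                        "mu_obs": float(mo),
                        "sigma_obs": float(so),
                        "mu_pred": float(mp),
                        "sigma_pred": float(sp),
                    }
                )
            obs_by_method[tag].extend(obs_m)
            pred_by_method[tag].extend(
                GaussianDist(float(m), float(s)) for m, s in zip(mu_m, sigmas)
            )

    pairs = {
        f"{alg_label}:{tag}": DistributionPairSet(obs_by_method[tag], pred_by_method[tag])
        for tag in error_methods
        if obs_by_method[tag]
    }
    kl = {label: mean_kl(ps) for label, ps in pairs.items()}
    states = {}
    for tag in error_methods:
        fr = frozen[tag]
        cal = fr.get("calibration")
        states[f"{alg_label}:{tag}"] = {
            "tag": tag,
            "uniform_sigma": fr.get("uniform_sigma"),
            "slope": None if cal is None else cal.slope,
            "intercept": None if cal is None else cal.intercept,
            "k": fr.get("k"),
            "sigma_floor": sigma_exp,
        }
    uniform = {
        f"{alg_label}:{tag}": frozen[tag]["uniform_sigma"]
        for tag in error_methods
        if tag in UNIFORM_TAGS
    }
    return GrowingWindowResult(
        predictions=pd.DataFrame(rows),
        pairs=pairs,
        mean_kl=kl,
        estimator_states=states,
        months=months_used,
        uniform_rmse=uniform,
    )
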