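"""Shared fixtures: small synthetic datasets and the drifting pipeline."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from qsarpd.distributions import DistributionPairSet, GaussianDist, mean_kl
from qsarpd.error_estimation import (
    ErrorEstimator,
    fit_error_regression,
    knn_mean_distance,
    make_variable_estimator,
    optimize_k,
)
from qsarpd.models import DescriptorScaler, double_loop_cv, fit, make_spec
from qsarpd.synthetic import SyntheticConfig, generate
from qsarpd.temporal import prepare_compound_table

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """A small temporally drifting dataset for harness-level tests."""
    config = SyntheticConfig(n_per_month=80, n_months=10, seed=3, drift=0.3)
    return config, generate(config)


def build_d2m_vs_ts_pipeline(
    seed: int,
    n_per_month: int = 500,
    n_months: int = 14,
    k_grid=(1, 2, 3, 5, 8, 12, 20, 50, 100, 200),
):
    """Drifting heteroscedastic fixture: ridge model, D2M-EUC vs uniform TS.

    Months 0-9 train (~5000 compounds), 10-11 parameterize (~1000),
    12-13 test (~1000).  Returns observed and predicted distribution
    lists for both error methods plus the frozen calibration.
    """
    config = SyntheticConfig(n_per_month=n_per_month, n_months=n_months, seed=seed)
    ds = generate(config)
    table = prepare_compound_table(ds.measurements, config.sigma_exp)
    table = table.merge(ds.descriptors, on="compound_id")
    month = dict(zip(ds.sidecar["compound_id"], ds.sidecar["month"]))
    table["month"] = table["compound_id"].map(month)
    desc_cols = [c for c in ds.descriptors.columns if c != "compound_id"]
    n_train_months = n_months - 4
    train = table[table["month"] < n_train_months]
    param = table[
        (table["month"] >= n_train_months) & (table["month"] < n_train_months + 2)
    ]
    test = table[table["month"] >= n_train_months + 2]

    def xy(df):
        return df[desc_cols].to_numpy(float), df["mu_obs"].to_numpy(float)

    X_tr, y_tr = xy(train)
    scaler = DescriptorScaler().fit(X_tr)
    Z_tr = scaler.transform(X_tr)
    model = fit(make_spec("ridge"), Z_tr, y_tr, seed=seed)

    X_pa, y_pa = xy(param)
    mu_pa = model.predict(scaler.transform(X_pa))
    obs_pa = [GaussianDist(m, s) for m, s in zip(param["mu_obs"], param["sigma_obs"])]
    sigma_exp = config.sigma_exp
    k = optimize_k(
        k_grid,
        "D2M-EUC",
        X_param=X_pa,
        mu_pred=mu_pa,
        observed=obs_pa,
        sigma_exp=sigma_exp,
        scaler=scaler,
        train_Z=Z_tr,
    )
    scores_pa = knn_mean_distance(scaler.transform(X_pa), Z_tr, k)
    calibration = fit_error_regression(scores_pa, y_pa - mu_pa, sigma_exp, k=k)
    d2m = make_variable_estimator(
        "D2M-EUC", sigma_exp, calibration=calibration, k=k, scaler=scaler, train_Z=Z_tr
    )
    ts = ErrorEstimator(
        tag="TS",
        sigma_floor=sigma_exp,
        uniform_sigma=float(np.sqrt(np.mean((y_pa - mu_pa) ** 2))),
    )

    cv_table = double_loop_cv(make_spec("ridge"), Z_tr, y_tr, 5, 5, seed=seed)

    X_te, y_te = xy(test)
    mu_te = model.predict(scaler.transform(X_te))
    obs_te = [GaussianDist(m, s) for m, s in zip(test["mu_obs"], test["sigma_obs"])]
    pred_d2m = [
        GaussianDist(float(m), float(s))
        for m, s in zip(mu_te, d2m.predict_sigma(X_te))
    ]
    pred_ts = [
        GaussianDist(float(m), float(s))
        for m, s in zip(mu_te, ts.predict_sigma(n=len(test)))
    ]
    return {
        "config": config,
        "dataset": ds,
        "obs_test": obs_te,
        "pred_d2m": pred_d2m,
        "pred_ts": pred_ts,
        "mean_kl_d2m": mean_kl(DistributionPairSet(obs_te, pred_d2m)),
        "mean_kl_ts": mean_kl(DistributionPairSet(obs_te, pred_ts)),
        "calibration": calibration,
        "k": k,
        "cv_rmse": cv_table.rmse(),
        "ts_rmse": ts.uniform_sigma,
        "observed_test_rmse": float(np.sqrt(np.mean((y_te - mu_te) ** 2))),
    }


@pytest.fixture(scope="session")
def hetero_pipeline():
    """The acceptance-scale drifting fixture (seed 0, ~5000/1000/1000)."""
    return build_d2m_vs_ts_pipeline(seed=0)
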