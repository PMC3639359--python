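"""Reliability indices, error calibration, and estimator composition."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from qsarpd.distributions import GaussianDist
from qsarpd.error_estimation import (
    ErrorCalibration,
    ErrorEstimator,
    MahalanobisMetric,
    bagged_variance_score,
    euclidean_distance,
    fit_error_regression,
    knn_mean_distance,
    local_error,
    mahalanobis_distance,
    make_uniform_estimator,
    make_variable_estimator,
    optimize_k,
)
from qsarpd.models import (
    CVPredictionTable,
    DescriptorScaler,
    fit,
    fit_bagged,
    make_spec,
)
import pandas as pd


def _cv_table(residuals):
    r = np.asarray(residuals, dtype=float)
    return CVPredictionTable(
        pd.DataFrame({"prediction": np.zeros_like(r), "residual": r, "abs_error": np.abs(r)})
    )


class TestDistances:
    def test_euclidean_3_4_5(self):
        assert euclidean_distance([0, 0], [3, 4]) == 5.0
        assert euclidean_distance([1, 2], [1, 2]) == 0.0

    def test_euclidean_permutation_invariance(self):
        a, b = np.array([1.0, -2.0, 3.0]), np.array([0.5, 0.5, -1.0])
        perm = [2, 0, 1]
        assert euclidean_distance(a[perm], b[perm]) == pytest.approx(
            euclidean_distance(a, b)
        )

    def test_euclidean_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            euclidean_distance([1, 2], [1, 2, 3])

    def test_mahalanobis_equals_euclidean_on_whitened_data(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3)) @ np.array([[2, 0.5, 0], [0, 1, 0.3], [0, 0, 0.7]])
        # exact whitening: the sample covariance of Z is the identity
        cov = np.cov(X, rowvar=False)
        w, U = np.linalg.eigh(cov)
        Z = (X - X.mean(0)) @ U / np.sqrt(w)
        a, b = Z[0], Z[1]
        assert mahalanobis_distance(a, b, Z) == pytest.approx(
            euclidean_distance(a, b), rel=1e-6
        )

    def test_mahalanobis_zero_for_identical_points(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        assert mahalanobis_distance(X[0], X[0], X) == pytest.approx(0.0, abs=1e-9)

    def test_mahalanobis_handles_rank_deficiency(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        X = np.column_stack([X, X[:, 0]])  # duplicated descriptor
        d = mahalanobis_distance(X[0], X[1], X)
        assert np.isfinite(d) and d > 0


class TestKNNScores:
    def test_query_on_training_row(self):
        X = np.array([[0.0], [1.0], [2.0]])
        assert knn_mean_distance(X[1], X, k=1) == 0.0

    def test_mean_of_k_smallest(self):
        train = np.array([[1.0], [2.0], [3.0]])
        assert knn_mean_distance(np.array([0.0]), train, k=2) == pytest.approx(1.5)
        assert knn_mean_distance(np.array([0.0]), train, k=3) == pytest.approx(2.0)

    def test_k_beyond_train_size_rejected(self):
        with pytest.raises(ValueError):
            knn_mean_distance(np.zeros(1), np.zeros((3, 1)), k=4)

    @pytest.mark.parametrize(
        "residuals,k,expected",
        [([-0.3, 5.0, 9.9], 1, 0.3), ([0.3, 0.4, 9.9], 2, np.sqrt(0.125)), ([0, 0, 0], 3, 0.0)],
    )
    def test_local_error_is_neighbor_rmse(self, residuals, k, expected):
        # training rows at distance 0, 1, 2 from the query
        train = np.array([[0.0], [1.0], [2.0]])
        got = local_error(np.array([0.0]), train, _cv_table(residuals), k=k)
        assert got == pytest.approx(expected)


class TestBaggedVariance:
    def test_sample_sd_of_member_predictions(self):
        from qsarpd.models import BaggedEnsemble

        class Stub:
            def __init__(self, v):
                self.v = v

            def predict(self, X):
                return np.full(len(X), self.v)

        ens = BaggedEnsemble([Stub(0.0), Stub(2.0)], [np.zeros(1)] * 2)
        assert bagged_variance_score(ens, np.zeros(2)) == pytest.approx(np.sqrt(2))
        shifted = BaggedEnsemble([Stub(5.0), Stub(7.0)], [np.zeros(1)] * 2)
        assert bagged_variance_score(shifted, np.zeros(2)) == pytest.approx(np.sqrt(2))


class TestErrorRegression:
    def test_zero_scores_rejected(self):
        with pytest.raises(ValueError):
            fit_error_regression(np.zeros(20), np.ones(20), 0.2)

    def test_sigma_at_zero_score_equals_sigma_exp(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 5, 100)
        r = rng.normal(size=100) * np.sqrt(0.1 * s + 0.04)
        cal = fit_error_regression(s, r, 0.2)
        assert cal.sigma(0.0) == pytest.approx(0.2)

    def test_recovers_planted_slope(self):
        """Var(residual) = 0.037*s + 0.04 over s in [0,10] at n=5000."""
        rng = np.random.default_rng(5)
        s = rng.uniform(0, 10, 5000)
        r = rng.normal(size=5000) * np.sqrt(0.037 * s + 0.04)
        cal = fit_error_regression(s, r, 0.2)
        assert cal.slope == pytest.approx(0.037, abs=0.005)
        assert cal.intercept == pytest.approx(0.04)

    def test_homoscedastic_residuals_clamp_to_zero_slope(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(0, 10, 5000)
        r = rng.normal(scale=0.2, size=5000)
        cal = fit_error_regression(s, r, 0.2)
        assert 0.0 <= cal.slope < 0.002

    def test_calibrated_sigma_nondecreasing_in_score(self):
        cal = ErrorCalibration(slope=0.05, intercept=0.04)
        scores = np.linspace(0, 10, 50)
        sig = cal.sigma(scores)
        assert np.all(np.diff(sig) >= 0)


class TestEstimators:
    @pytest.mark.parametrize(
        "pred,obs,expected",
        [
            ([0, 0], [1, 1], 1.0),
            ([0, 0], [0, 2], np.sqrt(2)),
            ([0], [0.7], 0.7),
        ],
    )
    def test_uniform_rmse(self, pred, obs, expected):
        est = make_uniform_estimator("TS", pred, obs, sigma_floor=0.01)
        assert est.uniform_sigma == pytest.approx(expected)
        assert np.allclose(est.predict_sigma(n=3), max(expected, 0.01))

    def test_uniform_requires_residuals(self):
        with pytest.raises(ValueError):
            make_uniform_estimator("CV", [], [], sigma_floor=0.1)

    def test_d2m_passes_score_through_calibration(self):
        cal = ErrorCalibration(slope=0.037, intercept=0.04)
        train = np.array([[0.0], [2.0]])
        est = make_variable_estimator(
            "D2M-EUC", 0.2, calibration=cal, k=1, train_Z=train
        )
        # query at distance 1 from its nearest neighbour
        got = est.predict_sigma(np.array([[1.0]]))
        assert got[0] == pytest.approx(np.sqrt(0.077))

    def test_bv_all_agreeing_ensemble_is_floored(self):
        X = np.arange(10.0)[:, None]
        ens = fit_bagged(
            make_spec("mean"), X, np.zeros(10), n_members=5, seed=0
        )
        est = make_variable_estimator("BV", 0.2, ensemble=ens)
        assert np.allclose(est.predict_sigma(X[:4]), 0.2)

    def test_le_uses_nearest_neighbor_residual(self):
        train = np.array([[0.0], [5.0]])
        est = make_variable_estimator(
            "LE-EUC", 0.1, k=1, train_Z=train, cv_table=_cv_table([0.5, 3.0])
        )
        assert est.predict_sigma(np.array([[0.2]]))[0] == pytest.approx(0.5)

    def test_missing_components_raise(self):
        with pytest.raises(ValueError):
            make_variable_estimator("BV", 0.2)  # no ensemble
        with pytest.raises(ValueError):
            make_variable_estimator("D2M-EUC", 0.2, k=3)  # no train_Z
        with pytest.raises(ValueError):
            make_variable_estimator("EM", 0.2)  # no error model

    def test_floor_dominance_across_methods(self):
        """Every emitted sigma is >= the experimental error."""
        rng = np.random.default_rng(7)
        train = rng.normal(size=(50, 3))
        y = train @ np.array([1.0, -0.5, 0.2]) + rng.normal(scale=0.05, size=50)
        queries = rng.normal(size=(20, 3))
        sigma_exp = 0.3
        cv = _cv_table(rng.normal(scale=0.05, size=50))
        ens = fit_bagged(make_spec("ridge"), train, y, n_members=8, seed=1)
        em = fit(make_spec("ridge"), train, np.abs(cv.residuals))
        cal = ErrorCalibration(slope=0.001, intercept=sigma_exp**2)
        estimators = [
            make_variable_estimator("D2M-EUC", sigma_exp, calibration=cal, k=3, train_Z=train),
            make_variable_estimator("LE-EUC", sigma_exp, k=5, train_Z=train, cv_table=cv),
            make_variable_estimator("BV", sigma_exp, ensemble=ens),
            make_variable_estimator("EM", sigma_exp, error_model=em),
            ErrorEstimator(tag="TS", sigma_floor=sigma_exp, uniform_sigma=0.01),
        ]
        for est in estimators:
            assert np.all(est.predict_sigma(queries, n=len(queries)) >= sigma_exp)


class TestOptimizeK:
    def _setup(self, seed=7, slope=1.5):
        rng = np.random.default_rng(seed)
        train = rng.uniform(-3, 3, size=(300, 2))
        queries = rng.uniform(-6, 6, size=(200, 2))
        scaler = DescriptorScaler().fit(train)
        Zt, Zq = scaler.transform(train), scaler.transform(queries)
        d1 = cdist(Zq, Zt).min(axis=1)
        y = rng.normal(size=200) * np.sqrt(slope * d1 + 0.04)
        obs = [GaussianDist(float(v), 0.2) for v in y]
        return scaler, Zt, queries, obs

    def test_single_candidate_returned(self):
        scaler, Zt, q, obs = self._setup()
        k = optimize_k(
            [4], "D2M-EUC", X_param=q, mu_pred=np.zeros(len(obs)), observed=obs,
            sigma_exp=0.2, scaler=scaler, train_Z=Zt,
        )
        assert k == 4

    def test_distance_driven_noise_selects_small_k(self):
        """When difficulty tracks the nearest-neighbour distance, small k wins."""
        scaler, Zt, q, obs = self._setup(seed=7)
        k = optimize_k(
            (1, 2, 3, 5, 8, 12, 20, 50, 100, 200),
            "D2M-EUC", X_param=q, mu_pred=np.zeros(len(obs)), observed=obs,
            sigma_exp=0.2, scaler=scaler, train_Z=Zt,
        )
        assert k <= 5

    def test_ties_resolve_to_smallest_k(self):
        """Constant CV residuals make every k equivalent for local error."""
        rng = np.random.default_rng(1)
        train = rng.normal(size=(30, 2))
        scaler = DescriptorScaler().fit(train)
        Zt = scaler.transform(train)
        cv = _cv_table(np.full(30, 0.4))
        q = rng.normal(size=(15, 2))
        obs = [GaussianDist(0.0, 0.2) for _ in range(15)]
        k = optimize_k(
            [2, 5, 9], "LE-EUC", X_param=q, mu_pred=np.zeros(15), observed=obs,
            sigma_exp=0.2, scaler=scaler, train_Z=Zt, cv_table=cv,
        )
        assert k == 2

    def test_oversized_candidates_filtered(self):
        scaler, Zt, q, obs = self._setup()
        with pytest.raises(ValueError):
            optimize_k(
                [10_000], "D2M-EUC", X_param=q, mu_pred=np.zeros(len(obs)),
                observed=obs, sigma_exp=0.2, scaler=scaler, train_Z=Zt,
            )

    def test_estimator_state_serialises(self):
        cal = ErrorCalibration(slope=0.05, intercept=0.04, k=3)
        est = make_variable_estimator(
            "D2M-EUC", 0.2, calibration=cal, k=3, train_Z=np.zeros((5, 2))
        )
        state = est.state_dict()
        assert state["slope"] == 0.05
        assert state["k"] == 3
        import json

        assert json.loads(est.state_json()) == state
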