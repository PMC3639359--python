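"""Temporal protocol: qualified values, training-set reduction, growing window."""

import numpy as np
import pandas as pd
import pytest

from qsarpd.temporal import (
    TemporalSplit,
    combined_test_set_size,
    parse_qualified_value,
    prepare_compound_table,
    reduce_training_set,
    run_growing_window,
)


class TestQualifiedValues:
    @pytest.mark.parametrize(
        "raw,value,qualifier",
        [
            (">5", 5.0, ">"),
            ("<-1.4", -1.4, "<"),
            ("3.2", 3.2, None),
            (">=0.5", 0.5, ">="),
            (" <= -2e-1 ", -0.2, "<="),
        ],
    )
    def test_qualifier_stripped_but_retained(self, raw, value, qualifier):
        got_value, got_qual = parse_qualified_value(raw)
        assert got_value == pytest.approx(value)
        assert got_qual == qualifier

    @pytest.mark.parametrize("raw", ["", "n/a", ">>5", "5..2", "about 3"])
    def test_unparseable_rejected(self, raw):
        with pytest.raises(ValueError):
            parse_qualified_value(raw)


class TestReduceTrainingSet:
    def _records(self, n):
        dates = pd.date_range("2009-01-01", periods=n, freq="h")
        return pd.DataFrame({"compound_id": np.arange(n), "date": dates})

    def test_below_cap_unchanged(self):
        records = self._records(3000)
        assert reduce_training_set(records, cap=3500, recent=2000, random_n=1500) is records

    def test_above_cap_keeps_all_newest(self):
        records = self._records(4000)
        out = reduce_training_set(records, cap=3500, recent=2000, random_n=1500, seed=0)
        assert len(out) == 3500
        newest = set(records.sort_values("date")["compound_id"].iloc[-2000:])
        assert newest <= set(out["compound_id"])

    def test_same_seed_same_subset(self):
        records = self._records(4000)
        a = reduce_training_set(records, 3500, 2000, 1500, seed=9)
        b = reduce_training_set(records, 3500, 2000, 1500, seed=9)
        assert list(a["compound_id"]) == list(b["compound_id"])

    def test_inconsistent_cap_rejected(self):
        with pytest.raises(ValueError):
            reduce_training_set(self._records(10), cap=100, recent=80, random_n=50)


class TestBookkeeping:
    def test_combined_counts_sum_monthly_windows(self):
        assert combined_test_set_size([10, 20, 30]) == 60
        assert combined_test_set_size({"m1": 5, "m2": 7}) == 12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            combined_test_set_size([5, -1])


class TestSplit:
    def test_monthly_windows_cover_post_param_range(self):
        dates = pd.Series(pd.to_datetime(["2010-01-15", "2011-02-10", "2011-04-20"]))
        split = TemporalSplit.from_dates(dates, "2011-01-01", "2011-02-01")
        assert [str(m.date()) for m in split.month_starts] == [
            "2011-02-01",
            "2011-03-01",
            "2011-04-01",
        ]

    def test_order_enforced(self):
        with pytest.raises(ValueError):
            TemporalSplit.from_dates(
                pd.Series(pd.to_datetime(["2011-01-01"])), "2011-06-01", "2011-01-01"
            )


class TestPrepareCompoundTable:
    def test_replicates_collapsed_with_eq4_sigma(self):
        measurements = pd.DataFrame(
            {
                "compound_id": ["a", "a", "b"],
                "date": ["2010-01-05", "2010-01-20", "2010-02-01"],
                "value": ["1.0", ">3.0", "-0.5"],
                "excluded": [0, 0, 0],
            }
        )
        table = prepare_compound_table(measurements, sigma_exp=0.2)
        row_a = table[table["compound_id"] == "a"].iloc[0]
        assert row_a["mu_obs"] == pytest.approx(2.0)
        assert row_a["sigma_obs"] == pytest.approx(0.2 / np.sqrt(2))
        assert row_a["date"] == pd.Timestamp("2010-01-05")

    def test_excluded_and_unparseable_rows_dropped(self):
        measurements = pd.DataFrame(
            {
                "compound_id": ["a", "b", "c"],
                "date": ["2010-01-05", "2010-01-06", "2010-01-07"],
                "value": ["1.0", "bad", "2.0"],
                "excluded": [0, 0, 1],
            }
        )
        table = prepare_compound_table(measurements, sigma_exp=0.2)
        assert list(table["compound_id"]) == ["a"]


@pytest.fixture(scope="module")
def result(small_dataset):
    config, ds = small_dataset
    return run_growing_window(
        ds.measurements,
        ds.descriptors,
        sigma_exp=config.sigma_exp,
        train_end="2010-07-01",
        param_end="2010-09-01",
        algorithm="ridge",
        error_methods=("TS", "CV", "D2M-EUC"),
        seed=5,
        outer_folds=4,
        inner_folds=3,
        k_grid=(1, 2, 3, 5, 10),
    )


class TestGrowingWindow:
    def test_predictions_cover_all_post_param_months(self, result):
        assert result.months == ["2010-09", "2010-10"]
        assert set(result.predictions["month"]) == {"2010-09", "2010-10"}

    def test_no_temporal_leak(self, result, small_dataset):
        """No test compound may appear in the training data of its own month."""
        _, ds = small_dataset
        first_date = (
            ds.measurements.groupby("compound_id")["date"].min().astype("datetime64[ns]")
        )
        for _, row in result.predictions.iterrows():
            month_start = pd.Period(row["month"], freq="M").to_timestamp()
            assert first_date[row["compound_id"]] >= month_start

    def test_calibration_frozen_across_run_repeats(self, small_dataset):
        config, ds = small_dataset
        kwargs = dict(
            sigma_exp=config.sigma_exp,
            train_end="2010-07-01",
            param_end="2010-09-01",
            algorithm="ridge",
            error_methods=("TS", "D2M-EUC"),
            seed=5,
            outer_folds=4,
            inner_folds=3,
            k_grid=(1, 2, 3, 5, 10),
        )
        a = run_growing_window(ds.measurements, ds.descriptors, **kwargs)
        b = run_growing_window(ds.measurements, ds.descriptors, **kwargs)
        assert a.estimator_states == b.estimator_states
        pd.testing.assert_frame_equal(a.predictions, b.predictions)

    def test_cv_rmse_underestimates_drifting_test_error(self, hetero_pipeline):
        """Random-fold CV is optimistic under drift; the temporal TS estimate is closer."""
        observed = hetero_pipeline["observed_test_rmse"]
        cv_est = hetero_pipeline["cv_rmse"]
        ts_est = hetero_pipeline["ts_rmse"]
        assert cv_est < observed
        assert abs(ts_est - observed) < abs(cv_est - observed)

    def test_unknown_error_method_rejected(self, small_dataset):
        config, ds = small_dataset
        with pytest.raises(ValueError):
            run_growing_window(
                ds.measurements,
                ds.descriptors,
                sigma_exp=config.sigma_exp,
                train_end="2010-07-01",
                param_end="2010-09-01",
                error_methods=("NOPE",),
            )
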