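"""Time aggregation, imputation, FDR filtering, bootstrap L1 importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from d2tra.das28 import measured_das28_records
from d2tra.feature_engineering import (
    LABEL_COLUMN,
    aggregate_timeseries,
    assemble_features,
    bootstrap_l1_importance,
    fdr_filter,
    impute_features,
    standardize_features,
)


class TestAggregateTimeseries:
    def test_constant_series(self):
        agg = aggregate_timeseries([2, 2, 2])
        assert agg["mean"] == 2 and agg["median"] == 2
        assert agg["sd"] == 0 and agg["mean_diff"] == 0 and agg["mean_minus_median"] == 0

    def test_arithmetic_progression(self):
        agg = aggregate_timeseries([1, 2, 3])
        assert agg["mean"] == 2 and agg["median"] == 2
        assert agg["sd"] == pytest.approx(1.0)
        assert agg["mean_diff"] == pytest.approx(1.0)
        assert agg["mean_minus_median"] == 0
        assert agg["min"] == 1 and agg["max"] == 3

    def test_singleton_leaves_sd_and_trend_undefined(self):
        agg = aggregate_timeseries([5])
        assert agg["mean"] == 5 and agg["median"] == 5
        assert np.isnan(agg["sd"]) and np.isnan(agg["mean_diff"])
        assert agg["mean_minus_median"] == 0

    def test_empty_series_all_missing(self):
        assert all(np.isnan(v) for v in aggregate_timeseries([]).values())

    def test_absolute_mode(self):
        agg = aggregate_timeseries([3, 1, 3], mean_diff_mode="absolute")
        assert agg["mean_diff"] == pytest.approx(2.0)

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_matches_brute_force(self, values):
        agg = aggregate_timeseries(values)
        v = np.array(values)
        assert agg["mean"] == pytest.approx(sum(values) / len(values), rel=1e-9, abs=1e-9)
        assert agg["median"] == pytest.approx(float(np.median(v)), rel=1e-9, abs=1e-9)
        diffs = [values[i + 1] - values[i] for i in range(len(values) - 1)]
        assert agg["mean_diff"] == pytest.approx(sum(diffs) / len(diffs), rel=1e-6, abs=1e-6)
        assert agg["mean_minus_median"] == pytest.approx(agg["mean"] - agg["median"], abs=1e-9)


class TestAssembleFeatures:
    def test_named_features_match_raw_data(self, default_cohort_60):
        bundle = default_cohort_60
        records = measured_das28_records(bundle)
        table = assemble_features(bundle, records, label_source="planted")
        assert len(table) == bundle.n_patients
        pid = table.index[0]
        rx = bundle.prescriptions
        assert table.loc[pid, "n_distinct_medications"] == rx[rx["patient_id"] == pid][
            "atc_code"
        ].nunique()
        esr = bundle.labs.query("patient_id == @pid and test_code == 'esr'")["value"]
        assert table.loc[pid, "lab_esr_max"] == pytest.approx(esr.max())
        diag = pd.Timestamp(
            bundle.patients.set_index("patient_id").loc[pid, "ra_diagnosis_date"]
        )
        ref = max(bundle.labs["datetime"].max(), bundle.visits["date"].max())
        expected_years = (pd.Timestamp(ref) - diag).days / 365.25
        assert table.loc[pid, "time_since_diagnosis_years"] == pytest.approx(expected_years)

    def test_das28_aggregates_present(self, default_cohort_60):
        records = measured_das28_records(default_cohort_60)
        table = assemble_features(default_cohort_60, records, label_source="planted")
        assert "das28_esr_mean" in table.columns

    def test_no_labeled_patients_raises(self, default_cohort_60):
        bundle = default_cohort_60.copy()
        bundle.patients["clinical_label"] = "unlabeled"
        with pytest.raises(ValueError, match="label"):
            assemble_features(bundle, [], label_source="clinical")


class TestStandardizeAndImpute:
    def test_standardized_columns_have_zero_mean_unit_sd(self, default_cohort_60):
        table = assemble_features(default_cohort_60, [], label_source="planted")
        std = standardize_features(table)
        X = std.drop(columns=[LABEL_COLUMN])
        complete = X.columns[X.notna().all()]
        assert len(complete) > 10
        assert np.allclose(X[complete].mean(), 0.0, atol=1e-9)
        assert np.allclose(X[complete].std(ddof=0), 1.0, atol=1e-9)

    def test_complete_table_returned_unchanged(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 0.0]})
        pd.testing.assert_frame_equal(impute_features(table), table)

    def test_linear_relation_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=300)
        table = pd.DataFrame({"x": x, "y": 2.0 * x + 1.0, "z": rng.normal(size=300)})
        missing = rng.random(300) < 0.2
        truth = table["y"].copy()
        table.loc[missing, "y"] = np.nan
        filled = impute_features(table, seed=0)
        err = np.abs(filled.loc[missing, "y"] - truth[missing])
        assert err.max() < 1e-6

    def test_imputed_values_within_observed_range(self):
        rng = np.random.default_rng(1)
        table = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        table.loc[rng.random(200) < 0.5, "d"] = np.nan
        filled = impute_features(table, seed=0)
        lo, hi = table["d"].min(), table["d"].max()
        assert filled["d"].between(lo - 1, hi + 1).all()

    def test_all_missing_column_rejected(self):
        table = pd.DataFrame({"a": [1.0, 2.0], "b": [np.nan, np.nan]})
        with pytest.raises(ValueError, match="all-missing"):
            impute_features(table)


def _null_table(rng, n=200, p=100):
    table = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"f{i}" for i in range(p)]
    )
    table[LABEL_COLUMN] = np.where(rng.random(n) < 0.5, "D2T", "nonD2T")
    return table


class TestFdrFilter:
    def test_alpha_zero_selects_nothing(self):
        table = _null_table(np.random.default_rng(0))
        assert fdr_filter(table, alpha=0.0) == []

    def test_single_class_rejected(self):
        table = _null_table(np.random.default_rng(0))
        table[LABEL_COLUMN] = "D2T"
        with pytest.raises(ValueError):
            fdr_filter(table)

    def test_strong_effect_always_selected(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            table = _null_table(rng, n=152, p=20)
            shift = (table[LABEL_COLUMN] == "D2T").astype(float) * 2.0
            table["f0"] = rng.normal(size=152) + shift
            assert "f0" in fdr_filter(table, alpha=0.05)

    def test_null_false_selection_controlled(self):
        # small-scale check; the full 300-replicate calibration runs in the
        # acceptance suite
        rng = np.random.default_rng(4)
        fdps = []
        for _ in range(60):
            selected = fdr_filter(_null_table(rng, n=100, p=50), alpha=0.05)
            fdps.append(1.0 if selected else 0.0)
        assert np.mean(fdps) <= 0.15


class TestBootstrapImportance:
    def _planted_table(self, rng, n=152, informative=10, noise=40, effect=1.0):
        y = np.array(["D2T"] * (n // 3) + ["nonD2T"] * (n - n // 3))
        rng.shuffle(y)
        cols = {}
        for i in range(informative):
            cols[f"signal_{i}"] = rng.normal(size=n) + effect * (y == "D2T")
        for i in range(noise):
            cols[f"noise_{i}"] = rng.normal(size=n)
        table = pd.DataFrame(cols)
        table[LABEL_COLUMN] = y
        return standardize_features(table)

    def test_fixed_seed_reports_identical(self):
        table = self._planted_table(np.random.default_rng(5))
        a = bootstrap_l1_importance(table, n_boot=1, seed=11)
        b = bootstrap_l1_importance(table, n_boot=1, seed=11)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_informative_features_outrank_noise(self):
        table = self._planted_table(np.random.default_rng(6))
        report = bootstrap_l1_importance(table, n_boot=50, seed=0)
        freq = report.table["selection_frequency"]
        signal = freq.filter(like="signal_")
        noise = freq.filter(like="noise_")
        assert signal.min() > noise.max()

    def test_too_few_rows_rejected(self):
        table = self._planted_table(np.random.default_rng(7), n=100)
        with pytest.raises(ValueError, match="rows"):
            bootstrap_l1_importance(table, train_size=140, test_size=12)

    def test_ranks_are_a_permutation(self):
        table = self._planted_table(np.random.default_rng(8))
        report = bootstrap_l1_importance(table, n_boot=10, seed=0)
        assert sorted(report.table["rank"]) == list(range(1, len(report.table) + 1))
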