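"""Censoring, monthly forward-fill grids, evaluation, model plumbing."""

import numpy as np
import pandas as pd
import pytest

from d2tra.d2t_rules import MoaTaxonomy
from d2tra.models import (
    DAYS_PER_MONTH,
    D2TPredictionModel,
    EvalReport,
    evaluate,
    regularize_timeline,
    truncate_before_first_btsdmard,
)
from d2tra.synthetic_ehr import GeneratorConfig, generate_cohort

TAX = MoaTaxonomy.default()


class TestTruncate:
    def test_only_pre_treatment_records_survive(self, default_cohort_60):
        bundle = default_cohort_60
        out = truncate_before_first_btsdmard(bundle, TAX)
        censor = out.censor_dates
        assert set(out.patients["patient_id"]) == set(censor)
        for table, col in (
            (out.labs, "datetime"),
            (out.clinical_measurements, "date"),
            (out.visits, "date"),
            (out.prescriptions, "start_date"),
        ):
            if len(table):
                limits = table["patient_id"].map(censor)
                assert (pd.to_datetime(table[col]) < limits).all()

    def test_patients_without_btsdmard_are_dropped(self, default_cohort_60):
        from d2tra.d2t_rules import moa_start_sequence

        bundle = default_cohort_60
        with_bts = {
            pid
            for pid, g in bundle.prescriptions.groupby("patient_id")
            if moa_start_sequence(g, TAX)
        }
        out = truncate_before_first_btsdmard(bundle, TAX)
        assert set(out.patients["patient_id"]) == with_bts


class TestRegularizeTimeline:
    def _obs(self, pairs, feature="esr"):
        t0 = pd.Timestamp("2015-01-01")
        return pd.DataFrame(
            {
                "date": [t0 + pd.Timedelta(days=m * DAYS_PER_MONTH) for m, _ in pairs],
                "feature": feature,
                "value": [v for _, v in pairs],
            }
        )

    def test_forward_fill_semantics(self):
        obs = self._obs([(0, 5.0), (3, 7.0)])
        censor = pd.Timestamp("2015-01-01") + pd.Timedelta(days=3.5 * DAYS_PER_MONTH)
        grid = regularize_timeline(obs, censor, "P1")
        assert grid.grid["esr"].tolist() == [5.0, 5.0, 5.0, 7.0]

    def test_single_observation_constant_grid(self):
        obs = self._obs([(0, 9.0)])
        censor = pd.Timestamp("2015-01-01") + pd.Timedelta(days=5.5 * DAYS_PER_MONTH)
        grid = regularize_timeline(obs, censor, "P1")
        assert grid.grid["esr"].tolist() == [9.0] * 6

    def test_no_observations_empty_grid(self):
        obs = self._obs([])
        grid = regularize_timeline(obs, "2016-01-01", "P1")
        assert grid.grid.empty

    def test_no_cell_on_or_after_censor(self):
        obs = self._obs([(0, 1.0), (2, 2.0), (10, 99.0)])
        censor = pd.Timestamp("2015-01-01") + pd.Timedelta(days=6 * DAYS_PER_MONTH)
        grid = regularize_timeline(obs, censor, "P1")
        assert 99.0 not in grid.grid["esr"].tolist()
        assert len(grid.grid) <= 7

    def test_never_fills_backward(self):
        obs = self._obs([(4, 3.0)])
        censor = pd.Timestamp("2015-01-01") + pd.Timedelta(days=8 * DAYS_PER_MONTH)
        grid = regularize_timeline(obs, censor, "P1")
        # the grid starts at the first observation, so nothing precedes it
        assert grid.grid["esr"].notna().all()
        assert len(grid.grid) <= 5


class TestEvaluate:
    def test_matches_hand_computed_ratios_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(0, 40, size=4)
            pred = ["D2T"] * (tp + fp) + ["nonD2T"] * (fn + tn)
            true = (
                ["D2T"] * tp + ["nonD2T"] * fp + ["D2T"] * fn + ["nonD2T"] * tn
            )
            report = evaluate(pred, true)
            assert (report.tp, report.fp, report.fn, report.tn) == (tp, fp, fn, tn)
            if tp + fn:
                assert report.sensitivity == pytest.approx(100 * tp / (tp + fn))
            if tn + fp:
                assert report.specificity == pytest.approx(100 * tn / (tn + fp))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate(["D2T"], ["D2T", "nonD2T"])


class TestPredictionModel:
    @pytest.fixture(scope="class")
    def bundle(self):
        # pre-treatment signal: hematology shifted by 0.8 SD from baseline on
        return generate_cohort(
            GeneratorConfig(
                n_patients=200, clinical_label_fraction=1.0, seed=17
            ).with_effect_scale(0.8)
        )

    def test_threshold_validation(self, bundle):
        model = D2TPredictionModel(bundle, TAX, label_source="planted")
        with pytest.raises(ValueError, match="threshold"):
            model.fit(threshold=0.0)
        with pytest.raises(ValueError, match="threshold"):
            model.fit(threshold=1.5)

    def test_threshold_one_predicts_nothing_positive(self, bundle):
        model = D2TPredictionModel(bundle, TAX, label_source="planted")
        results = model.fit(threshold=1.0, n_folds=5, seed=0)
        assert results.report.tp == 0 and results.report.fp == 0
        assert results.report.sensitivity == 0.0

    def test_signal_above_chance(self, bundle):
        results = D2TPredictionModel(bundle, TAX, label_source="planted").fit(
            threshold=0.15, n_folds=5, seed=0
        )
        assert results.report.auc > 0.65

    def test_post_censor_data_never_leaks(self, bundle):
        """Perturbing every record after the censor date leaves the
        prediction feature matrix bit-identical."""
        perturbed = bundle.copy()
        censor = truncate_before_first_btsdmard(bundle, TAX).censor_dates
        labs = perturbed.labs
        mask = labs["patient_id"].isin(censor) & (
            pd.to_datetime(labs["datetime"]) >= labs["patient_id"].map(censor)
        )
        labs.loc[mask, "value"] = labs.loc[mask, "value"] * 10 + 123.4
        cm = perturbed.clinical_measurements
        mask_cm = cm["patient_id"].isin(censor) & (
            pd.to_datetime(cm["date"]) >= cm["patient_id"].map(censor)
        )
        cm.loc[mask_cm, "vas_gh"] = 55.0
        a = D2TPredictionModel(bundle, TAX, label_source="planted").X
        b = D2TPredictionModel(perturbed, TAX, label_source="planted").X
        pd.testing.assert_frame_equal(a, b)
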