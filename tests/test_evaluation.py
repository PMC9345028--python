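"""Confusion-matrix arithmetic, binary reduction, CV structure, horizons."""

import numpy as np
import pandas as pd
import pytest

from bgdecomp.evaluation import (GROUP_3CLASS, binary_metrics,
                                 binary_reduction, class_metrics, confusion,
                                 cross_validate, horizon_summary,
                                 importance_report, ratio_percent)


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        y = [0, 1, 2, 3, 4, 2, 1]
        cm = confusion(y, y)
        assert (np.diag(cm.counts) == [1, 2, 2, 1, 1]).all()
        assert cm.counts.to_numpy().sum() == len(y)

    def test_grouping_collapses_by_partition_sum(self):
        y_true = [0, 1, 2, 3, 4, 4]
        y_pred = [0, 1, 3, 4, 2, 0]
        cm5 = confusion(y_true, y_pred)
        cm3 = confusion(y_true, y_pred, grouping=GROUP_3CLASS)
        assert cm3.counts.shape == (3, 3)
        assert cm3.counts.loc[2, 2] == 3  # all hyper-hyper cells merge
        assert cm3.counts.to_numpy().sum() == cm5.counts.to_numpy().sum()

    def test_row_percentages_match_hand_arithmetic(self):
        counts = pd.DataFrame([[8, 1, 1], [2, 6, 2], [0, 5, 5]],
                              index=[0, 1, 2], columns=[0, 1, 2])
        y_true = sum([[t] * counts.loc[t].sum() for t in counts.index], [])
        y_pred = sum([[p] * counts.loc[t, p] for t in counts.index
                      for p in counts.columns], [])
        cm = confusion(y_true, y_pred)
        pd.testing.assert_frame_equal(cm.counts, counts,
                                      check_names=False)
        assert cm.row_percent.loc[0, 0] == pytest.approx(80.0)
        assert cm.row_percent.loc[2, 1] == pytest.approx(50.0)
        assert cm.row_percent.sum(axis=1).round(10).eq(100).all()

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion([0, 9], [0, 0], labels=[0, 1])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0])


class TestClassMetrics:
    def test_metrics_agree_with_direct_arithmetic(self):
        y_true = [0] * 50 + [1] * 30 + [2] * 20
        rng = np.random.default_rng(0)
        y_pred = rng.integers(0, 3, size=100)
        cm = confusion(y_true, y_pred)
        for cls in (0, 1, 2):
            tp, fp, fn, tn = cm.ovr_counts(cls)
            m = class_metrics(cm, cls)
            assert m.sensitivity == pytest.approx(
                100 * tp / (tp + fn), abs=1e-12)
            assert m.specificity == pytest.approx(
                100 * tn / (tn + fp), abs=1e-12)
            assert m.precision == pytest.approx(
                100 * tp / (tp + fp), abs=1e-12)
            assert m.balanced_accuracy == pytest.approx(
                (m.sensitivity + m.specificity) / 2, abs=1e-12)

    def test_undefined_precision_is_missing(self):
        cm = confusion([1, 1, 0], [0, 0, 0], labels=[0, 1])
        m = class_metrics(cm, 1)
        assert np.isnan(m.precision)
        assert m.sensitivity == 0.0

    def test_ratio_percent_half_up(self):
        assert ratio_percent(1, 8, 2) == 12.5
        assert ratio_percent(1, 3, 2) == 33.33
        assert ratio_percent(5, 1000, 1) == 0.5
        assert ratio_percent(15, 200, 1) == 7.5
        assert ratio_percent(125, 1000, 1) == 12.5
        assert np.isnan(ratio_percent(1, 0))


class TestBinaryReduction:
    def test_partition(self):
        np.testing.assert_array_equal(binary_reduction([0, 1, 2, 3, 4]),
                                      [0, 1, 1, 1, 1])

    def test_cross_category_confusion_counts_correct(self):
        # true 3 predicted 2: both decompensated -> counted correct
        m = binary_metrics([3, 0], [2, 1])
        assert m.sensitivity == 100.0
        assert m.specificity == 0.0

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            binary_reduction([5])

    def test_binary_sensitivity_at_least_max_class_sensitivity(
            self, prepared):
        """Union of decompensation classes can only gain sensitivity."""
        rng = np.random.default_rng(1)
        y_true = prepared.features["target"].to_numpy()
        y_pred = np.where(rng.random(len(y_true)) < 0.3,
                          rng.integers(0, 5, len(y_true)), y_true)
        cm = confusion(y_true, y_pred, labels=[0, 1, 2, 3, 4])
        per_class = [class_metrics(cm, c).sensitivity for c in (1, 2, 3, 4)]
        b = binary_metrics(y_true, y_pred)
        assert b.sensitivity >= max(per_class)


class TestCrossValidate:
    def _oracle(self, train, test):
        # noisy oracle predictor: right 80% of the time, seeded by fold size
        rng = np.random.default_rng(len(train))
        y = test["target"].to_numpy()
        wrong = rng.random(len(y)) < 0.2
        return np.where(wrong, (y + 1) % 5, y)

    def test_k_folds_and_summary_structure(self, prepared):
        per_fold, summary = cross_validate(prepared.features, self._oracle,
                                           k=5, seed=0)
        assert len(per_fold) == 5
        assert {"mean", "sd"} == set(summary.columns)
        assert "sensitivity_1" in per_fold.columns

    def test_deterministic_given_seed(self, prepared):
        a, _ = cross_validate(prepared.features, self._oracle, k=3, seed=2)
        b, _ = cross_validate(prepared.features, self._oracle, k=3, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_k_below_two_rejected(self, prepared):
        with pytest.raises(ValueError):
            cross_validate(prepared.features, self._oracle, k=1)


class TestHorizonSummary:
    def test_median_of_three(self):
        manifest = pd.DataFrame({
            "case_id": ["a", "b", "c"], "category": [1, 1, 1],
            "window_start": [0.0] * 3, "window_end": [20.0, 30.0, 40.0],
            "horizon_hours": [3.0, 7.0, 15.0], "n_rows": [2] * 3})
        out = horizon_summary(manifest).set_index("category")
        assert out.loc[1, "horizon_hours_median"] == 7.0
        assert out.loc[1, "horizon_hours_q1"] == 5.0

    def test_fixed_gap_recovered(self):
        manifest = pd.DataFrame({
            "case_id": [f"c{i}" for i in range(9)], "category": [2] * 9,
            "window_start": [0.0] * 9,
            "window_end": np.linspace(20, 60, 9),
            "horizon_hours": [4.0] * 9, "n_rows": [3] * 9})
        out = horizon_summary(manifest).set_index("category")
        assert out.loc[2, "horizon_hours_median"] == 4.0

    def test_empty_category_absent(self):
        manifest = pd.DataFrame({
            "case_id": ["a"], "category": [0], "window_start": [0.0],
            "window_end": [48.0], "horizon_hours": [np.nan], "n_rows": [5]})
        out = horizon_summary(manifest)
        assert list(out["category"]) == [0]
        assert np.isnan(out.iloc[0]["horizon_hours_median"])

    def test_pipeline_horizons_match_ground_truth_gaps(self, small_cohort,
                                                       prepared):
        """Horizons recomputed directly from ground truth agree with the
        manifest."""
        from conftest import ground_truth_hours
        from bgdecomp.labeling import add_hours
        from bgdecomp.preprocessing import apply_lab_limits

        gt = ground_truth_hours(small_cohort)
        lab = add_hours(apply_lab_limits(small_cohort.lab),
                        small_cohort.admissions)
        expected = {}
        for _, row in gt.iterrows():
            h = lab.loc[lab["case_id"] == row["case_id"], "hours"]
            prior = h[h < row["event_hours"]]
            expected[(row["case_id"], row["category"])] = \
                row["event_hours"] - prior.max()
        manifest = prepared.manifest.query("category > 0")
        for _, row in manifest.iterrows():
            key = (row["case_id"], row["category"])
            assert row["horizon_hours"] == pytest.approx(expected[key])


def test_importance_report_columns(model_stub_ensemble):
    report, union = importance_report(model_stub_ensemble, top_k=3)
    assert report.shape == (3, 5)
    assert len(union) >= 3


@pytest.fixture
def model_stub_ensemble():
    from test_ecoc import _stub_candidates
    from bgdecomp.ecoc import EnsembleSpec

    cands, X, _ = _stub_candidates(seed=3, n=10)
    rng = np.random.default_rng(0)
    for m in cands:
        m.importance = pd.Series(rng.random(6),
                                 index=[f"f{i}" for i in range(6)])
    return EnsembleSpec(models=cands)
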