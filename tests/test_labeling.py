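"""Category boundaries, first-event detection, windows, inclusion rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bgdecomp.labeling import (CategoryScheme, build_lookback,
                               build_windows_manifest, categorize_bg,
                               categorize_bg_array, compute_horizon,
                               detect_events_cohort, detect_first_events,
                               meets_inclusion_criteria)
from bgdecomp.preprocessing import apply_lab_limits

from conftest import ground_truth_hours, make_case_labs

BOUNDARY_CASES = [(3.89, 1), (3.9, 0), (10.0, 0), (10.01, 2),
                  (13.9, 2), (13.91, 3), (16.7, 3), (16.71, 4)]


class TestCategorize:
    @pytest.mark.parametrize("value,expected", BOUNDARY_CASES)
    def test_boundary_values(self, value, expected):
        assert categorize_bg(value) == expected

    def test_vectorised_agrees(self):
        vals = [v for v, _ in BOUNDARY_CASES]
        expected = [c for _, c in BOUNDARY_CASES]
        assert list(categorize_bg_array(vals)) == expected

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_non_positive_rejected(self, bad):
        with pytest.raises(ValueError):
            categorize_bg(bad)

    @given(st.floats(min_value=0.01, max_value=60.0))
    def test_total_and_interval_consistent(self, value):
        """Every positive value maps to exactly the interval it lies in."""
        cat = categorize_bg(value)
        scheme = CategoryScheme()
        if value < scheme.hypo:
            assert cat == 1
        elif value <= scheme.mild:
            assert cat == 0
        elif value <= scheme.moderate:
            assert cat == 2
        elif value <= scheme.severe:
            assert cat == 3
        else:
            assert cat == 4

    def test_misordered_thresholds_rejected(self):
        with pytest.raises(ValueError):
            CategoryScheme(hypo=11.0)


def _bg_series(points):
    return make_case_labs([("glucose", v, h) for h, v in points])


class TestDetectFirstEvents:
    def test_first_crossing_only(self):
        events = detect_first_events(_bg_series([(2, 5.0), (10, 3.5),
                                                 (20, 3.1)]))
        assert len(events) == 1
        assert events.iloc[0]["category"] == 1
        assert events.iloc[0]["event_hours"] == 10

    def test_event_at_first_measurement_voided(self):
        events = detect_first_events(_bg_series([(0, 18.0), (5, 6.0)]))
        assert events.empty

    def test_voiding_applies_to_whole_category(self):
        """A later recurrence of a voided category is not promoted."""
        events = detect_first_events(_bg_series([(0, 18.0), (5, 6.0),
                                                 (9, 17.5)]))
        assert events.empty

    def test_escalating_series(self):
        labs = _bg_series([(1, 11.0), (2, 15.0), (3, 17.0)])
        events = detect_first_events(labs)
        # h1 is the first measurement, so the category-2 event is voided
        assert dict(zip(events["category"], events["event_hours"])) == \
            {3: 2.0, 4: 3.0}
        labs2 = make_case_labs([("sodium", 140.0, 0.5)] ).pipe(
            lambda d: pd.concat([d, _bg_series([(1, 11.0), (2, 15.0),
                                                (3, 17.0)])],
                                ignore_index=True))
        events2 = detect_first_events(labs2)
        assert dict(zip(events2["category"], events2["event_hours"])) == \
            {2: 1.0, 3: 2.0, 4: 3.0}

    def test_no_bg_measurements_empty(self):
        labs = make_case_labs([("sodium", 140.0, 1.0)])
        assert detect_first_events(labs).empty

    def test_first_measurement_mode_bg(self):
        labs = pd.concat([make_case_labs([("sodium", 140.0, 0.5)]),
                          _bg_series([(1, 11.0), (5, 6.0)])],
                         ignore_index=True)
        assert len(detect_first_events(labs, first_measurement="any")) == 1
        assert detect_first_events(labs, first_measurement="bg").empty

    def test_cohort_detection_recovers_ground_truth(self, small_cohort):
        lab = apply_lab_limits(small_cohort.lab)
        events = detect_events_cohort(lab, small_cohort.admissions)
        gt = ground_truth_hours(small_cohort)
        merged = gt.merge(events, on=["case_id", "category"],
                          suffixes=("_gt", ""))
        assert len(merged) == len(gt) == len(events)
        np.testing.assert_allclose(merged["event_hours_gt"],
                                   merged["event_hours"], atol=1e-9)


class TestLookbackAndHorizon:
    def test_strict_precedence(self):
        labs = _bg_series([(2, 5.0), (5, 6.0), (10, 3.5), (12, 5.5)])
        window = build_lookback(labs, event_hours=10.0)
        assert sorted(window["hours"]) == [2.0, 5.0]

    def test_control_window_is_full_stay(self):
        labs = _bg_series([(2, 5.0), (12, 6.0)])
        window = build_lookback(labs, event_hours=None)
        assert len(window) == 2

    def test_single_prior_datum_horizon(self):
        labs = _bg_series([(2, 5.0), (10, 3.5)])
        window = build_lookback(labs, event_hours=10.0)
        assert len(window) == 1
        assert compute_horizon(window, 10.0) == pytest.approx(8.0)

    def test_event_without_prior_data_excluded(self):
        labs = _bg_series([(10, 3.5), (12, 5.0)])
        with pytest.raises(ValueError, match="excluded"):
            build_lookback(labs.query("hours >= 10"), event_hours=10.0)

    def test_horizon_invariant_under_post_event_data(self):
        labs = _bg_series([(2, 5.0), (3, 6.0), (10, 3.5)])
        more = pd.concat([labs, _bg_series([(11, 4.0), (20, 5.0)])],
                         ignore_index=True)
        h1 = compute_horizon(build_lookback(labs, 10.0), 10.0)
        h2 = compute_horizon(build_lookback(more, 10.0), 10.0)
        assert h1 == h2 == pytest.approx(7.0)

    def test_manifest_controls_and_events(self, small_cohort):
        lab = apply_lab_limits(small_cohort.lab)
        events = detect_events_cohort(lab, small_cohort.admissions)
        manifest = build_windows_manifest(lab, small_cohort.admissions,
                                          events)
        event_cases = set(events["case_id"])
        controls = manifest.query("category == 0")
        assert set(controls["case_id"]).isdisjoint(event_cases)
        assert set(controls["case_id"]) | event_cases == \
            set(small_cohort.admissions["case_id"])
        evt = manifest.query("category > 0")
        assert (evt["horizon_hours"] >= 0).all()
        assert controls["horizon_hours"].isna().all()


def _patient(labs=None, dx=None, drugs=None):
    labs = pd.DataFrame(labs or [], columns=["analyte", "value"])
    dx = pd.DataFrame({"icd10_code": dx or []})
    drugs = pd.DataFrame({"atc_code": drugs or []})
    return labs, dx, drugs


class TestInclusionCriteria:
    def test_hba1c_pct_alone_includes(self):
        ok, rules = meets_inclusion_criteria(
            *_patient(labs=[("hba1c", 6.5)]))
        assert ok and rules == ["extreme_glucose"]

    def test_single_extreme_bg_includes(self):
        ok, _ = meets_inclusion_criteria(*_patient(labs=[("glucose", 11.1)]))
        assert ok
        ok2, _ = meets_inclusion_criteria(*_patient(labs=[("glucose", 3.9)]))
        assert ok2

    def test_normoglycemic_no_codes_excluded(self):
        ok, rules = meets_inclusion_criteria(
            *_patient(labs=[("glucose", 5.0), ("glucose", 9.0)]))
        assert not ok and rules == []

    def test_diagnosis_and_drug_rules(self):
        ok, rules = meets_inclusion_criteria(*_patient(dx=["E11.9"]))
        assert ok and rules == ["diagnosis"]
        ok2, rules2 = meets_inclusion_criteria(*_patient(drugs=["A10BA02"]))
        assert ok2 and rules2 == ["antidiabetic_drug"]

    def test_fasting_and_ogtt_thresholds(self):
        assert meets_inclusion_criteria(
            *_patient(labs=[("glucose_fasting", 7.0)]))[0]
        assert meets_inclusion_criteria(
            *_patient(labs=[("ogtt_2h", 11.1)]))[0]
        assert not meets_inclusion_criteria(
            *_patient(labs=[("glucose_fasting", 6.9)]))[0]
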