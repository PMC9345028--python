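"""Derived-variable statistics, feature assembly, hashing and leakage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from bgdecomp.features import (CategoryEncoding, assemble_features,
                               dedup_rows, summarize_analyte)


class TestSummarizeAnalyte:
    def test_hand_arithmetic(self):
        s = summarize_analyte([1, 2, 3], [4.0, 6.0, 8.0])
        assert s["mean"] == pytest.approx(6.0)
        assert s["sd"] == pytest.approx(2.0)
        assert s["range"] == pytest.approx(4.0)
        assert s["iqr"] == pytest.approx(2.0)
        assert s["count"] == 3
        assert s["recent"] == 8.0
        assert s["extreme"] == 8.0  # |8-6| ties |4-6|; later wins

    def test_empty_series(self):
        s = summarize_analyte([], [])
        assert s["count"] == 0
        assert all(np.isnan(s[k]) for k in s if k != "count")

    def test_single_value_semantics(self):
        s = summarize_analyte([5.0], [7.2])
        assert s["count"] == 1
        assert s["mean"] == s["extreme"] == s["recent"] == 7.2
        assert all(np.isnan(s[k]) for k in ("sd", "iqr", "range", "trend"))

    def test_trend_is_slope_of_last_three_points(self):
        s = summarize_analyte([1, 2, 3, 4], [5.0, 5.0, 5.0, 9.0])
        # OLS through (2,5),(3,5),(4,9): slope 2.0 units/hour
        assert s["trend"] == pytest.approx(2.0)
        assert s["extreme"] == 9.0

    def test_trend_missing_below_two_points(self):
        assert np.isnan(summarize_analyte([1.0], [3.0])["trend"])

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(-50, 50)),
                    min_size=2, max_size=12, unique_by=lambda tv: tv[0]))
    def test_order_free_stats_permutation_invariant(self, pairs):
        pairs_sorted = sorted(pairs)
        hours = np.array([p[0] for p in pairs_sorted])
        vals = np.array([p[1] for p in pairs_sorted])
        a = summarize_analyte(hours, vals)
        rng = np.random.default_rng(0)
        # permute which hour each value is observed at: order-free stats
        # depend only on the multiset of values
        b = summarize_analyte(hours, rng.permutation(vals))
        for key in ("mean", "sd", "iqr", "range", "count"):
            assert a[key] == pytest.approx(b[key], nan_ok=True)

    def test_recent_and_trend_depend_on_order(self):
        a = summarize_analyte([1, 2, 3], [1.0, 2.0, 9.0])
        b = summarize_analyte([1, 2, 3], [9.0, 2.0, 1.0])
        assert a["recent"] != b["recent"]
        assert a["trend"] != b["trend"]
        for key in ("mean", "sd", "iqr", "range", "count"):
            assert a[key] == pytest.approx(b[key])


def _mini_tables():
    adm = pd.DataFrame({
        "case_id": ["C1", "C2"], "patient_id": ["P1", "P1"],
        "admit_time": pd.to_datetime(["2018-01-01", "2018-02-01"]),
        "discharge_time": pd.to_datetime(["2018-01-04", "2018-02-05"])})
    lab = pd.DataFrame({
        "case_id": ["C1"] * 3 + ["C2"] * 3,
        "analyte": ["glucose", "sodium", "glucose"] * 2,
        "value": [5.0, 140.0, 3.5, 6.0, 138.0, 6.5],
        "time": pd.to_datetime([
            "2018-01-01 02:00", "2018-01-01 03:00", "2018-01-02 00:00",
            "2018-02-01 10:00", "2018-02-02 10:00", "2018-02-03 10:00"])})
    demo = pd.DataFrame({
        "patient_id": ["P1"], "age": [70.0], "sex": ["F"],
        "height_cm": [165.0], "weight_kg": [70.0], "language": ["de"],
        "civil_status": ["married"]})
    drug = pd.DataFrame({
        "case_id": ["C1", "C1"], "atc_code": ["A10BA02", "C07AB02"],
        "time": pd.to_datetime(["2017-12-20 00:00", "2018-01-01 05:00"]),
        "pre_admission": [1, 0]})
    dx = pd.DataFrame({"patient_id": ["P1"], "icd10_code": ["E11.9"],
                       "time": pd.to_datetime(["2017-06-01"])})
    icu = pd.DataFrame({
        "case_id": ["C1"], "icu_start": pd.to_datetime(["2018-01-01 06:00"]),
        "icu_end": pd.to_datetime(["2018-01-02 06:00"])})
    events = pd.DataFrame({"case_id": ["C1"], "category": [1],
                           "event_hours": [22.0], "bg_value": [3.5]})
    manifest = pd.DataFrame({
        "case_id": ["C1", "C2"], "category": [1, 0],
        "window_start": [0.0, 0.0], "window_end": [22.0, 96.0],
        "horizon_hours": [19.0, np.nan], "n_rows": [2, 3]})
    return dict(lab=lab, admissions=adm, demographics=demo, drug=drug,
                diagnosis=dx, icu=icu, events=events), manifest


class TestAssembleFeatures:
    def test_event_window_excludes_event_row(self):
        tables, manifest = _mini_tables()
        feats, _ = assemble_features(manifest, **tables)
        c1 = feats.loc[feats["case_id"] == "C1"].iloc[0]
        assert c1["glucose__count"] == 1  # the 3.5 event row is excluded
        assert c1["glucose__recent"] == 5.0
        assert c1["target"] == 1

    def test_control_window_uses_all_rows(self):
        tables, manifest = _mini_tables()
        feats, _ = assemble_features(manifest, **tables)
        c2 = feats.loc[feats["case_id"] == "C2"].iloc[0]
        assert c2["glucose__count"] == 2
        assert c2["target"] == 0

    def test_history_and_context_features(self):
        tables, manifest = _mini_tables()
        feats, _ = assemble_features(manifest, **tables)
        c1 = feats.loc[feats["case_id"] == "C1"].iloc[0]
        assert c1["add_a10b_pre"] == 1.0
        assert c1["add_a10a_pre"] == 0.0
        assert c1["dx_diabetes"] == 1.0
        assert c1["icu_stay"] == 1.0
        # C2 (a later admission of the same patient) sees C1's event
        c2 = feats.loc[feats["case_id"] == "C2"].iloc[0]
        assert c2["prev_decomp_cat1"] == 1.0
        # C1's own event does not flag itself as previous
        assert c1["prev_decomp_cat1"] == 0.0

    def test_control_of_never_decompensated_case_has_no_prev(self):
        tables, manifest = _mini_tables()
        tables["events"] = tables["events"].iloc[:0]
        manifest = manifest.assign(category=[0, 0])
        feats, _ = assemble_features(manifest, **tables)
        assert (feats[[f"prev_decomp_cat{c}" for c in (1, 2, 3, 4)]]
                .to_numpy() == 0).all()

    def test_missing_table_error_names_it(self):
        tables, manifest = _mini_tables()
        tables["drug"] = None
        with pytest.raises(ValueError, match="drug"):
            assemble_features(manifest, **tables)

    def test_duplicate_rows_removed_and_dedup_idempotent(self):
        tables, manifest = _mini_tables()
        doubled = pd.concat([manifest, manifest], ignore_index=True)
        feats, _ = assemble_features(doubled, **tables)
        assert len(feats) == 2  # byte-identical duplicates collapse
        again = dedup_rows(feats)
        pd.testing.assert_frame_equal(again, feats)

    def test_rows_differing_in_one_stat_both_kept(self):
        tables, manifest = _mini_tables()
        feats, _ = assemble_features(manifest, **tables)
        assert feats["row_hash"].nunique() == 2

    def test_dedup_keeps_k_of_nk_duplicates(self):
        tables, manifest = _mini_tables()
        feats, _ = assemble_features(manifest, **tables,
                                     deduplicate=False)
        stacked = pd.concat([feats] * 4, ignore_index=True)
        assert len(dedup_rows(stacked)) == len(set(feats["row_hash"]))

    def test_post_event_perturbation_changes_nothing(self):
        """Leakage guard at the unit level: data at/after the event time is
        invisible to the event instance's features."""
        tables, manifest = _mini_tables()
        feats, _ = assemble_features(manifest, **tables)
        perturbed = tables["lab"].copy()
        post = perturbed["time"] >= pd.Timestamp("2018-01-01 22:00")
        post &= perturbed["case_id"] == "C1"
        perturbed.loc[post, "value"] *= 1.7
        tables2 = {**tables, "lab": perturbed}
        feats2, _ = assemble_features(manifest, **tables2)
        c1a = feats.loc[feats["case_id"] == "C1", "row_hash"].iloc[0]
        c1b = feats2.loc[feats2["case_id"] == "C1", "row_hash"].iloc[0]
        assert c1a == c1b


def test_category_encoding_round_trip():
    demo = pd.DataFrame({"sex": ["M", "F"], "language": ["de", "fr"],
                         "civil_status": ["single", "married"]})
    enc = CategoryEncoding.fit(demo)
    restored = CategoryEncoding.from_json(enc.to_json())
    assert restored.mapping == enc.mapping
    coded = restored.encode(demo)
    assert coded["sex"].tolist() == [1, 0]
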