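"""Derived feature vectors from look-back windows.

Each modeling instance — a (case, target category) pair with a look-back
window — is summarised into a fixed-width row: eight descriptive statistics
per laboratory analyte (mean, SD, IQR, total range, recent trend, most
extreme value, most recent value, analysis count), patient demographics,
antidiabetic-drug history split pre-admission vs in-stay by ATC A10
subcode, previous-decompensation indicators per category, diagnosis
history, ICU stay, and outlier-flag aggregates. Rows are hashed and
deduplicated.

Statistics are intentionally simple, mimicking a clinician scanning a chart
rather than a learned representation:

* SD is the sample SD; IQR is Q3 - Q1 with linear-interpolation quantiles;
  range is max - min.
* recent trend is the ordinary-least-squares slope (units/hour) over the
  last ``min(3, count)`` points, missing when fewer than two points exist.
* most extreme value is the observation maximising |x - window mean|, ties
  resolved toward the later observation.

With a single observation the SD/IQR/range/trend are missing and mean =
extreme = recent = the value; with none, only the count (0) is defined.
Features never read data at or after the event time.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .labeling import DIABETES_ICD_PREFIXES, add_hours

__all__ = ["summarize_analyte", "assemble_features", "dedup_rows",
           "CategoryEncoding", "ANALYTE_STATS", "ID_COLUMNS",
           "feature_columns"]

ANALYTE_STATS = ("mean", "sd", "iqr", "range", "trend", "extreme",
                 "recent", "count")
ID_COLUMNS = ("case_id", "patient_id", "target", "row_hash")

_A10_SUBCODES = ("A10A", "A10B", "A10X")


def summarize_analyte(hours, values) -> dict[str, float]:
    """The eight descriptive statistics of one time-value series.

    ``hours``/``values`` must be sorted by time; either may be empty. A
    total function: undefined statistics come back as NaN.
    """
    hours = np.asarray(hours, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(values)
    out = dict.fromkeys(ANALYTE_STATS, np.nan)
    out["count"] = float(n)
    if n == 0:
        return out
    mean = float(values.mean())
    out["mean"] = mean
    out["recent"] = float(values[-1])
    absdev = np.abs(values - mean)
    # tie toward the later observation
    out["extreme"] = float(values[(len(values) - 1)
                                  - int(np.argmax(absdev[::-1]))])
    if n >= 2:
        out["sd"] = float(values.std(ddof=1))
        q1, q3 = np.percentile(values, [25.0, 75.0])
        out["iqr"] = float(q3 - q1)
        out["range"] = float(values.max() - values.min())
        ht, vt = hours[-min(3, n):], values[-min(3, n):]
        den = float(((ht - ht.mean()) ** 2).sum())
        if den > 0:
            out["trend"] = float(
                ((ht - ht.mean()) * (vt - vt.mean())).sum() / den)
    return out


@dataclass
class CategoryEncoding:
    """Stable integer codes for categorical demographics.

    Tree models need a fixed encoding across training and prediction; the
    map is fitted once and persisted with the model bundle.
    """

    mapping: dict[str, dict[str, int]] = field(default_factory=dict)

    COLUMNS = ("sex", "language", "civil_status")

    @classmethod
    def fit(cls, demographics: pd.DataFrame) -> "CategoryEncoding":
        mapping = {}
        for col in cls.COLUMNS:
            vals = sorted(demographics[col].dropna().astype(str).unique())
            mapping[col] = {v: i for i, v in enumerate(vals)}
        return cls(mapping)

    def encode(self, demographics: pd.DataFrame) -> pd.DataFrame:
        out = demographics.copy()
        for col, codes in self.mapping.items():
            out[col] = out[col].astype(str).map(codes)
        return out

    def to_json(self) -> str:
        return json.dumps(self.mapping, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "CategoryEncoding":
        return cls(json.loads(text))


def _require(table: pd.DataFrame | None, name: str) -> pd.DataFrame:
    if table is None:
        raise ValueError(f"missing required table: {name}")
    return table


def _hash_rows(df: pd.DataFrame, cols: list[str]) -> pd.Series:
    """64-bit non-cryptographic digest of the canonicalised row string."""
    def fmt(v):
        if pd.isna(v):
            return ""
        if isinstance(v, float):
            return format(v, ".10g")
        return str(v)

    def one(row) -> str:
        payload = ";".join(fmt(v) for v in row)
        return hashlib.blake2b(payload.encode(), digest_size=8).hexdigest()

    return pd.Series([one(r) for r in df[cols].itertuples(index=False)],
                     index=df.index, name="row_hash")


def assemble_features(manifest: pd.DataFrame, *, lab: pd.DataFrame,
                      admissions: pd.DataFrame, demographics: pd.DataFrame,
                      drug: pd.DataFrame, diagnosis: pd.DataFrame,
                      icu: pd.DataFrame, events: pd.DataFrame,
                      outlier_flags: pd.Series | None = None,
                      analytes: list[str] | None = None,
                      encoding: CategoryEncoding | None = None,
                      deduplicate: bool = True,
                      ) -> tuple[pd.DataFrame, CategoryEncoding]:
    """Derive one feature row per modeling instance in ``manifest``.

    ``manifest`` comes from :func:`bgdecomp.labeling.build_windows_manifest`;
    ``events`` is the cohort events table (used for previous-decompensation
    indicators only, restricted to strictly before each window's end).
    Returns the wide feature table and the categorical encoding used.
    """
    for name, tbl in (("lab", lab), ("admissions", admissions),
                      ("demographics", demographics), ("drug", drug),
                      ("diagnosis", diagnosis), ("icu", icu),
                      ("events", events)):
        _require(tbl, name)

    inst = manifest.reset_index(drop=True).copy()
    inst["iid"] = np.arange(len(inst))
    labh = add_hours(lab, admissions)
    if outlier_flags is not None:
        labh = labh.assign(outlier_flag=outlier_flags.reindex(
            lab.index).fillna(0).astype(int).to_numpy())
    else:
        labh = labh.assign(outlier_flag=0)
    if analytes is None:
        analytes = sorted(labh["analyte"].unique())

    # --- window rows: strict precedence for event windows, full stay for
    # controls ---------------------------------------------------------------
    m = labh.merge(inst[["iid", "case_id", "category", "window_end"]],
                   on="case_id", how="inner")
    m = m.loc[(m["category"] == 0) | (m["hours"] < m["window_end"])]
    m = m.sort_values(["iid", "analyte", "hours"], kind="stable")

    grp = m.groupby(["iid", "analyte"], sort=True)
    stats = grp["value"].agg(count="count", mean="mean", sd="std",
                             vmin="min", vmax="max")
    stats["iqr"] = (grp["value"].quantile(0.75)
                    - grp["value"].quantile(0.25))
    stats["range"] = stats["vmax"] - stats["vmin"]
    stats["recent"] = grp["value"].last()

    absdev = (m["value"] - grp["value"].transform("mean")).abs()
    m2 = m.assign(absdev=absdev).sort_values(
        ["iid", "analyte", "absdev", "hours"], kind="stable")
    stats["extreme"] = m2.groupby(["iid", "analyte"], sort=True)[
        "value"].last()

    tail = grp.tail(3)
    tg = tail.groupby(["iid", "analyte"], sort=True)
    ht = tail["hours"] - tg["hours"].transform("mean")
    vt = tail["value"] - tg["value"].transform("mean")
    aux = tail.assign(num=ht * vt, den=ht * ht)
    sums = aux.groupby(["iid", "analyte"], sort=True)[["num", "den"]].sum()
    stats["trend"] = np.where(sums["den"] > 0,
                              sums["num"] / sums["den"], np.nan)

    single = stats["count"] == 1
    stats.loc[single, ["sd", "iqr", "range", "trend"]] = np.nan
    stats = stats.drop(columns=["vmin", "vmax"])
    stats["count"] = stats["count"].astype(float)

    wide = stats[list(ANALYTE_STATS)].unstack("analyte")
    wide.columns = [f"{a}__{s}" for s, a in wide.columns]
    full_cols = [f"{a}__{s}" for a in analytes for s in ANALYTE_STATS]
    wide = wide.reindex(columns=full_cols).reindex(inst["iid"])
    count_cols = [f"{a}__count" for a in analytes]
    wide[count_cols] = wide[count_cols].fillna(0.0)

    # --- outlier flag aggregates -------------------------------------------
    oflags = grp["outlier_flag"].max().rename("oflag")
    owide = oflags.unstack("analyte") if len(oflags) else pd.DataFrame()
    owide = owide.reindex(columns=analytes).reindex(inst["iid"]).fillna(0.0)
    owide.columns = [f"{a}__outlier" for a in analytes]
    ototal = m.groupby("iid")["outlier_flag"].sum().reindex(
        inst["iid"]).fillna(0.0)

    out = pd.concat([inst.set_index("iid")[["case_id", "category"]],
                     wide, owide], axis=1)
    out["outlier_total"] = ototal
    out["n_obs"] = m.groupby("iid").size().reindex(inst["iid"]).fillna(0.0)
    out["window_end_hours"] = inst.set_index("iid")["window_end"]

    # --- demographics -------------------------------------------------------
    enc = encoding or CategoryEncoding.fit(demographics)
    demo = enc.encode(demographics).set_index("patient_id")
    pat = admissions.set_index("case_id")["patient_id"]
    out["patient_id"] = out["case_id"].map(pat)
    for col in ("age", "height_cm", "weight_kg", "sex", "language",
                "civil_status"):
        out[col] = out["patient_id"].map(demo[col])

    # --- drug history by A10 subcode ---------------------------------------
    drugh = add_hours(drug, admissions)
    dm = drugh.merge(inst[["iid", "case_id", "category", "window_end"]],
                     on="case_id", how="inner")
    pre = dm.loc[dm["pre_admission"] == 1]
    instay = dm.loc[(dm["pre_admission"] == 0)
                    & ((dm["category"] == 0)
                       | (dm["hours"] < dm["window_end"]))]
    for sub in _A10_SUBCODES:
        pre_hit = pre.loc[pre["atc_code"].str.startswith(sub)]
        in_hit = instay.loc[instay["atc_code"].str.startswith(sub)]
        out[f"add_{sub.lower()}_pre"] = (
            out.index.isin(pre_hit["iid"]).astype(float))
        out[f"add_{sub.lower()}_instay"] = (
            out.index.isin(in_hit["iid"]).astype(float))

    # --- previous decompensation per category ------------------------------
    admit = admissions.set_index("case_id")["admit_time"]
    ev = events.copy()
    ev["abs_time"] = ev["case_id"].map(admit) + pd.to_timedelta(
        ev["event_hours"], unit="h")
    ev["patient_id"] = ev["case_id"].map(pat)
    inst_abs = (inst["case_id"].map(admit)
                + pd.to_timedelta(inst["window_end"], unit="h"))
    pm = inst.assign(patient_id=inst["case_id"].map(pat),
                     end_abs=inst_abs).merge(
        ev[["patient_id", "category", "abs_time"]].rename(
            columns={"category": "prev_cat"}),
        on="patient_id", how="left")
    prior = pm.loc[pm["abs_time"] < pm["end_abs"]]
    for c in (1, 2, 3, 4):
        hit = prior.loc[prior["prev_cat"] == c, "iid"].unique()
        out[f"prev_decomp_cat{c}"] = out.index.isin(hit).astype(float)

    # --- diagnosis history --------------------------------------------------
    dx = diagnosis.copy()
    dx["is_dm"] = dx["icd10_code"].astype(str).str.startswith(
        DIABETES_ICD_PREFIXES)
    per_pat = dx.groupby("patient_id").agg(dx_diabetes=("is_dm", "any"),
                                           n_diagnoses=("is_dm", "size"))
    out["dx_diabetes"] = out["patient_id"].map(
        per_pat["dx_diabetes"]).eq(True).astype(float)
    out["n_diagnoses"] = out["patient_id"].map(
        per_pat["n_diagnoses"]).fillna(0).astype(float)

    # --- ICU ----------------------------------------------------------------
    icuh = icu.copy()
    icuh["icu_start_h"] = ((icuh["icu_start"] - icuh["case_id"].map(admit))
                           / pd.Timedelta(hours=1))
    im = inst.merge(icuh[["case_id", "icu_start_h"]], on="case_id",
                    how="inner")
    im = im.loc[(im["category"] == 0)
                | (im["icu_start_h"] < im["window_end"])]
    out["icu_stay"] = out.index.isin(im["iid"]).astype(float)

    out = out.rename(columns={"category": "target"})
    out = out.reset_index(drop=True)

    feat_cols = [c for c in out.columns
                 if c not in ("case_id", "patient_id", "target")]
    out["row_hash"] = _hash_rows(out, feat_cols + ["target"])
    if deduplicate:
        out = dedup_rows(out)
    return out, enc


def dedup_rows(features: pd.DataFrame) -> pd.DataFrame:
    """Drop duplicate feature rows by hash, keeping the first occurrence."""
    return features.drop_duplicates(
        subset="row_hash", keep="first").reset_index(drop=True)


def feature_columns(features: pd.DataFrame) -> list[str]:
    """Names of the model-input columns of an assembled feature table."""
    return [c for c in features.columns if c not in ID_COLUMNS]
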