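"""Blood-glucose category assignment, event detection and look-back windows.

The clinical category scheme partitions positive BG values (mmol/L) into:

====================  ========  =======================
interval              category  decompensation type
====================  ========  =======================
>= 3.9 to <= 10       0         nondecompensated
< 3.9                 1         hypoglycemia (level 1)
> 10 to <= 13.9       2         mild hyperglycemia
> 13.9 to <= 16.7     3         moderate hyperglycemia
> 16.7                4         severe hyperglycemia
====================  ========  =======================

Only the first event per (case, category) counts. An event coinciding with
the case's first measurement is not considered at all for that category —
there is nothing before it to predict from — and voids the category for the
case. Times are continuous hours since admission; look-back windows are
half-open ``[admission, event)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CategoryScheme", "DEFAULT_SCHEME", "CATEGORY_NAMES",
    "categorize_bg", "categorize_bg_array", "detect_first_events",
    "detect_events_cohort", "add_hours", "build_lookback", "compute_horizon",
    "build_windows_manifest", "meets_inclusion_criteria",
    "DIABETES_ICD_PREFIXES",
]

log = logging.getLogger(__name__)

CATEGORY_NAMES = {
    0: "nondecompensated",
    1: "hypoglycemia",
    2: "mild hyperglycemia",
    3: "moderate hyperglycemia",
    4: "severe hyperglycemia",
}


@dataclass(frozen=True)
class CategoryScheme:
    """Boundary-exact BG category thresholds (mmol/L)."""

    hypo: float = 3.9
    mild: float = 10.0
    moderate: float = 13.9
    severe: float = 16.7

    def __post_init__(self) -> None:
        if not self.hypo < self.mild < self.moderate < self.severe:
            raise ValueError("thresholds must be strictly increasing")

    def categorize(self, value: float) -> int:
        if not value > 0:
            raise ValueError(f"BG value must be positive, got {value}")
        if value < self.hypo:
            return 1
        if value <= self.mild:
            return 0
        if value <= self.moderate:
            return 2
        if value <= self.severe:
            return 3
        return 4

    def categorize_array(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if not (values > 0).all():
            raise ValueError("BG values must be positive")
        return np.select(
            [values < self.hypo, values <= self.mild,
             values <= self.moderate, values <= self.severe],
            [1, 0, 2, 3], default=4).astype(int)


DEFAULT_SCHEME = CategoryScheme()


def categorize_bg(value: float, scheme: CategoryScheme = DEFAULT_SCHEME) -> int:
    """Assign the BG category (0-4) of a single value in mmol/L."""
    return scheme.categorize(value)


def categorize_bg_array(values, scheme: CategoryScheme = DEFAULT_SCHEME
                        ) -> np.ndarray:
    return scheme.categorize_array(values)


def add_hours(table: pd.DataFrame, admissions: pd.DataFrame,
              time_col: str = "time") -> pd.DataFrame:
    """Attach continuous hours since admission to a case-keyed table."""
    admit = admissions.set_index("case_id")["admit_time"]
    out = table.copy()
    out["hours"] = (out[time_col] - out["case_id"].map(admit)
                    ) / pd.Timedelta(hours=1)
    return out


def detect_first_events(case_labs: pd.DataFrame,
                        scheme: CategoryScheme = DEFAULT_SCHEME,
                        bg_analyte: str = "glucose",
                        first_measurement: str = "any") -> pd.DataFrame:
    """First decompensation event per category for a single case.

    ``case_labs`` needs columns analyte/value/hours. ``first_measurement``
    selects what counts as the case's first measurement time: ``"any"``
    (earliest timestamp of any analyte, the default) or ``"bg"`` (earliest
    BG measurement). A category whose first event falls on that timestamp is
    voided for the case and omitted from the result.

    Returns a frame with columns category, event_hours, bg_value.
    """
    empty = pd.DataFrame({"category": pd.Series(dtype=int),
                          "event_hours": pd.Series(dtype=float),
                          "bg_value": pd.Series(dtype=float)})
    bg = case_labs.loc[case_labs["analyte"] == bg_analyte]
    if bg.empty:
        return empty
    if first_measurement not in ("any", "bg"):
        raise ValueError("first_measurement must be 'any' or 'bg'")
    base = case_labs if first_measurement == "any" else bg
    first_time = float(base["hours"].min())
    bg = bg.sort_values("hours", kind="stable")
    cats = scheme.categorize_array(bg["value"].to_numpy())
    rows = []
    for c in (1, 2, 3, 4):
        hit = np.flatnonzero(cats == c)
        if len(hit) == 0:
            continue
        t = float(bg["hours"].iloc[hit[0]])
        if t == first_time:
            continue  # detected with the first measurements: voided
        rows.append((c, t, float(bg["value"].iloc[hit[0]])))
    if not rows:
        return empty
    return pd.DataFrame(rows, columns=["category", "event_hours", "bg_value"])


def detect_events_cohort(lab: pd.DataFrame, admissions: pd.DataFrame,
                         scheme: CategoryScheme = DEFAULT_SCHEME,
                         bg_analyte: str = "glucose",
                         first_measurement: str = "any") -> pd.DataFrame:
    """Vectorised first-event detection across all cases.

    Returns columns case_id, category, event_hours, bg_value.
    """
    if first_measurement not in ("any", "bg"):
        raise ValueError("first_measurement must be 'any' or 'bg'")
    labh = add_hours(lab, admissions)
    bg = labh.loc[labh["analyte"] == bg_analyte].copy()
    if bg.empty:
        return pd.DataFrame({"case_id": pd.Series(dtype=str),
                             "category": pd.Series(dtype=int),
                             "event_hours": pd.Series(dtype=float),
                             "bg_value": pd.Series(dtype=float)})
    bg["category"] = scheme.categorize_array(bg["value"].to_numpy())
    base = labh if first_measurement == "any" else bg
    first_time = base.groupby("case_id")["hours"].min()
    dec = bg.loc[bg["category"] > 0]
    first = (dec.sort_values("hours", kind="stable")
                .groupby(["case_id", "category"], as_index=False)
                .first())
    at_first = first["hours"].to_numpy() == first["case_id"].map(
        first_time).to_numpy()
    events = first.loc[~at_first, ["case_id", "category", "hours", "value"]]
    events = events.rename(columns={"hours": "event_hours",
                                    "value": "bg_value"})
    return events.sort_values(["case_id", "category"],
                              kind="stable").reset_index(drop=True)


def build_lookback(case_labs: pd.DataFrame,
                   event_hours: float | None) -> pd.DataFrame:
    """Rows of the look-back window.

    Event windows contain data strictly before the event; control windows
    (``event_hours=None``) contain the full stay.
    """
    if event_hours is None:
        return case_labs.copy()
    window = case_labs.loc[case_labs["hours"] < event_hours]
    if window.empty:
        raise ValueError("event has no preceding data; case excluded "
                         "for this category")
    return window.copy()


def compute_horizon(window: pd.DataFrame, event_hours: float) -> float:
    """Prediction horizon: hours from the last predictor datum to the event."""
    if window.empty:
        raise ValueError("empty look-back window has no horizon")
    horizon = event_hours - float(window["hours"].max())
    return max(horizon, 0.0)


def build_windows_manifest(lab: pd.DataFrame, admissions: pd.DataFrame,
                           events: pd.DataFrame) -> pd.DataFrame:
    """One modeling instance per (case, category) plus per-case controls.

    Event instances get ``window_end`` = event time (exclusive) and a
    prediction horizon; cases with no considered event contribute one
    control instance (category 0) spanning the full stay. Columns:
    case_id, category, window_start, window_end, horizon_hours, n_rows.
    """
    labh = add_hours(lab, admissions)
    los = admissions.set_index("case_id")
    los_h = ((los["discharge_time"] - los["admit_time"])
             / pd.Timedelta(hours=1))
    hours = labh.groupby("case_id")["hours"]
    last_before: dict[tuple[str, int], float] = {}
    rows = []
    case_hours = {cid: g.to_numpy() for cid, g in hours}
    for _, ev in events.iterrows():
        h = case_hours.get(ev["case_id"])
        if h is None:
            continue
        prior = h[h < ev["event_hours"]]
        if len(prior) == 0:
            continue
        rows.append((ev["case_id"], int(ev["category"]), 0.0,
                     float(ev["event_hours"]),
                     float(ev["event_hours"] - prior.max()), len(prior)))
    event_cases = set(events["case_id"])
    for cid in los.index:
        if cid in event_cases:
            continue
        h = case_hours.get(cid)
        n = 0 if h is None else len(h)
        rows.append((cid, 0, 0.0, float(los_h[cid]), np.nan, n))
    manifest = pd.DataFrame(
        rows, columns=["case_id", "category", "window_start", "window_end",
                       "horizon_hours", "n_rows"])
    return manifest.sort_values(["case_id", "category"],
                                kind="stable").reset_index(drop=True)


#: ICD-10 prefixes of diabetes and diabetes-related syndromes used by the
#: cohort inclusion rules.
DIABETES_ICD_PREFIXES = (
    "E10", "E11", "E12", "E13", "E14", "E16", "E66", "E67", "E68",
    "G59", "G63", "H28", "H36", "K77.8", "K85", "M14.2", "N08.3",
    "O24", "R73", "R81",
)

#: analyte name -> inclusion-rule measurement semantics
_INCLUSION_ANALYTES = {
    "glucose": "bg",
    "glucose_fasting": "fasting_bg",
    "ogtt_2h": "ogtt_2h",
    "hba1c": "hba1c_pct",
    "hba1c_ifcc": "hba1c_mmolmol",
}


def meets_inclusion_criteria(patient_labs: pd.DataFrame,
                             patient_diagnoses: pd.DataFrame,
                             patient_drugs: pd.DataFrame,
                             ) -> tuple[bool, list[str]]:
    """Dysglycemia-risk cohort inclusion check for one patient.

    A patient qualifies when at least one rule fires:

    1. a diabetes/diabetes-related ICD-10 diagnosis,
    2. administration of an ATC class A10 (antidiabetic) drug,
    3. an extreme glucose-related laboratory result: BG < 4.0 or
       >= 11.1 mmol/L at any time, fasting venous BG >= 7.0 mmol/L, 2-h OGTT
       >= 11.1 mmol/L, or HbA1c >= 48 mmol/mol / >= 6.5%.

    Returns (included, list of triggered rule names).
    """
    fired: list[str] = []
    codes = patient_diagnoses.get("icd10_code",
                                  pd.Series(dtype=str)).astype(str)
    if codes.str.startswith(DIABETES_ICD_PREFIXES).any():
        fired.append("diagnosis")
    atc = patient_drugs.get("atc_code", pd.Series(dtype=str)).astype(str)
    if atc.str.startswith("A10").any():
        fired.append("antidiabetic_drug")
    if not patient_labs.empty:
        kind = patient_labs["analyte"].map(_INCLUSION_ANALYTES)
        v = patient_labs["value"]
        extreme = (
            ((kind == "bg") & ((v < 4.0) | (v >= 11.1)))
            | ((kind == "fasting_bg") & (v >= 7.0))
            | ((kind == "ogtt_2h") & (v >= 11.1))
            | ((kind == "hba1c_pct") & (v >= 6.5))
            | ((kind == "hba1c_mmolmol") & (v >= 48.0)))
        if extreme.any():
            fired.append("extreme_glucose")
    return bool(fired), fired
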