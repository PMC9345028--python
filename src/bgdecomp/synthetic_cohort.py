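"""Synthetic inpatient cohort with injected blood-glucose decompensation events.

Emulates the data sources the prediction pipeline consumes: per-patient
demographics, admissions, irregularly sampled laboratory time series, drug
administrations (ATC-coded), diagnoses (ICD-10), ICU stays — plus a ground
truth table of injected decompensation events (category 1-4, time, BG value)
that the pipeline itself never reads.

Design highlights
-----------------
* Laboratory sampling times follow an inhomogeneous Poisson process with a
  daytime-peaked intensity, mimicking routine ward blood draws.
* Blood glucose follows an Ornstein-Uhlenbeck process around a per-case
  set-point, clipped to the nondecompensated band; injected events are the
  only measurements outside that band, so ground truth is exactly
  recoverable by first-event detection.
* A configurable subset of "signal" analytes shifts linearly over the hours
  preceding an injected event, with category-specific signs, giving the
  classifier a known signal to recover (and none when ``signal_strength=0``).
* Decompensation ends a latent baseline course whose duration is drawn from
  the same distribution as control stays; the event then extends the stay.
  Window length is therefore uninformative about the outcome by design.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AnalyteSpec",
    "CohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "inject_event",
    "DEFAULT_PANEL",
    "DEFAULT_SIGNAL_SIGNATURE",
    "EVENT_VALUE_RANGES",
]

BASE_TIME = pd.Timestamp("2018-01-01 00:00:00")

#: Nondecompensated band within which background glucose is confined.
GLUCOSE_SAFE_BAND = (4.2, 9.6)

#: BG intervals (mmol/L) from which injected event values are drawn; each is
#: strictly inside the corresponding clinical category interval.
EVENT_VALUE_RANGES: Mapping[int, tuple[float, float]] = {
    1: (2.6, 3.8),     # hypoglycemia: < 3.9
    2: (10.3, 13.6),   # mild hyperglycemia: > 10 to <= 13.9
    3: (14.1, 16.5),   # moderate hyperglycemia: > 13.9 to <= 16.7
    4: (17.0, 22.0),   # severe hyperglycemia: > 16.7
}


@dataclass(frozen=True)
class AnalyteSpec:
    """Reference distribution and sampling rate for one laboratory analyte.

    Means/SDs are order-of-magnitude plausible for adult inpatients but are
    invented for simulation purposes and not clinically calibrated.
    """

    name: str
    mean: float
    sd: float
    rate_per_day: float


def _panel() -> tuple[AnalyteSpec, ...]:
    rows = [
        # name, mean, sd, samples/day
        ("glucose", 6.1, 0.9, 4.0),
        ("sodium", 140.0, 3.0, 1.2),
        ("potassium", 4.2, 0.45, 1.2),
        ("chloride", 103.0, 4.0, 1.0),
        ("bicarbonate", 24.0, 2.5, 0.8),
        ("ph", 7.40, 0.04, 0.8),
        ("base_excess", 0.0, 2.5, 0.8),
        ("pco2", 5.3, 0.8, 0.8),
        ("po2", 11.0, 2.0, 0.8),
        ("lactate", 1.6, 0.6, 2.0),
        ("creatinine", 85.0, 25.0, 1.0),
        ("urea", 6.5, 2.2, 0.9),
        ("egfr", 75.0, 20.0, 0.7),
        ("crp", 25.0, 12.0, 2.0),
        ("procalcitonin", 0.4, 0.15, 0.3),
        ("leukocytes", 8.5, 2.5, 2.0),
        ("hemoglobin", 130.0, 16.0, 1.0),
        ("hematocrit", 0.40, 0.05, 1.0),
        ("erythrocytes", 4.5, 0.5, 0.8),
        ("thrombocytes", 250.0, 70.0, 0.8),
        ("mcv", 90.0, 5.0, 0.6),
        ("albumin", 38.0, 5.0, 0.6),
        ("total_protein", 68.0, 6.0, 0.5),
        ("calcium", 2.3, 0.12, 0.8),
        ("magnesium", 0.85, 0.10, 2.0),
        ("phosphate", 1.05, 0.20, 2.0),
        ("bilirubin_total", 12.0, 4.0, 0.5),
        ("alat", 35.0, 11.0, 0.6),
        ("asat", 32.0, 10.0, 0.6),
        ("ggt", 45.0, 15.0, 0.5),
        ("alp", 80.0, 25.0, 0.4),
        ("lipase", 45.0, 15.0, 0.3),
        ("amylase", 60.0, 20.0, 0.2),
        ("ldh", 220.0, 50.0, 0.4),
        ("ck", 110.0, 36.0, 0.3),
        ("troponin_t", 0.020, 0.006, 0.4),
        ("nt_probnp", 300.0, 100.0, 0.2),
        ("tsh", 2.2, 0.7, 0.15),
        ("hba1c", 6.1, 0.9, 0.12),
        ("triglycerides", 1.6, 0.5, 0.2),
        ("cholesterol_total", 4.8, 1.0, 0.2),
        ("hdl_cholesterol", 1.3, 0.3, 0.2),
        ("ldl_cholesterol", 2.8, 0.8, 0.2),
        ("ferritin", 180.0, 60.0, 0.15),
        ("transferrin", 2.5, 0.4, 0.15),
        ("iron", 15.0, 5.0, 0.15),
        ("inr", 1.10, 0.15, 0.6),
        ("aptt", 30.0, 5.0, 0.5),
        ("fibrinogen", 3.5, 0.8, 0.3),
        ("d_dimer", 0.9, 0.3, 0.3),
        ("osmolality", 290.0, 6.0, 0.3),
        ("uric_acid", 320.0, 80.0, 0.2),
    ]
    return tuple(AnalyteSpec(*r) for r in rows)


#: Default 52-analyte panel.
DEFAULT_PANEL: tuple[AnalyteSpec, ...] = _panel()

#: Per-analyte, per-category sign of the pre-event shift. Categories not
#: listed do not move that analyte. The patterns are chosen so that each
#: decompensation category has a distinct multivariate signature, which a
#: feature-importance recovery test can rank.
DEFAULT_SIGNAL_SIGNATURE: Mapping[str, Mapping[int, float]] = {
    "lactate": {1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0},
    "crp": {1: 1.0},
    "leukocytes": {2: 1.0, 3: 1.0, 4: 1.0},
    "potassium": {3: 1.0, 4: 1.0},
    "phosphate": {4: 1.0},
    "magnesium": {1: -1.0, 2: 1.0, 3: 1.0, 4: 1.0},
}

_ANTIDIABETIC_ATC = (
    "A10AB01", "A10AB04", "A10AC01", "A10AD01", "A10AE04",
    "A10BA02", "A10BB01", "A10BB12", "A10BH01", "A10BJ02", "A10BK01",
)
_OTHER_ATC = (
    "C07AB02", "C09AA05", "C10AA05", "N02BE01", "J01CA04",
    "B01AC06", "B01AB05", "A02BC02", "N05BA06", "R03AC02",
)
_DIABETES_ICD = (
    "E10.9", "E11.9", "E11.65", "E13.9", "E14.9", "E16.2",
    "E66.0", "O24.4", "R73.0", "R73.9",
)
_OTHER_ICD = (
    "I10", "I21.4", "I48.0", "I50.1", "J18.9", "J44.1",
    "K29.7", "N17.9", "M54.5", "F05",
)
_LANGUAGES = ("de", "fr", "it", "en")
_CIVIL = ("single", "married", "widowed", "divorced")


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for cohort generation.

    Parameters mirror the characteristics of the real inpatient cohort the
    pipeline targets: per-admission decompensation prevalences of
    12.8/42.1/16.4/13.3% for categories 1-4, a 52-analyte laboratory panel,
    ~1.66 admissions per patient, and sparse per-case analyte panels.
    """

    n_patients: int = 1200
    extra_admissions_mean: float = 0.66
    category_prevalences: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.128, 2: 0.421, 3: 0.164, 4: 0.133}
    )
    analyte_panel: tuple[AnalyteSpec, ...] = DEFAULT_PANEL
    signal_signature: Mapping[str, Mapping[int, float]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNAL_SIGNATURE)
    )
    #: Effect size (in analyte SD units, reached at event time) of the
    #: pre-event shift of signal analytes. 0 produces a null cohort.
    signal_strength: float = 1.5
    #: Hours before the event over which the shift ramps up linearly.
    signal_window_hours: float = 12.0
    #: Probability that an analyte is part of a given case's panel.
    analyte_inclusion_prob: float = 0.6
    los_median_days: float = 3.8
    los_sigma: float = 0.7
    recovery_median_days: float = 2.5
    recovery_sigma: float = 0.5
    min_course_hours: float = 12.0
    icu_prob: float = 0.15
    #: Rate of deliberately implausible entries, exercising plausibility
    #: cleaning downstream (never applied to glucose).
    corruption_prob: float = 0.004
    allow_multi_category: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if not self.analyte_panel:
            raise ValueError("analyte panel must be non-empty")
        prev = dict(self.category_prevalences)
        if set(prev) - {1, 2, 3, 4}:
            raise ValueError("prevalence categories must be in {1,2,3,4}")
        for c, p in prev.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for category {c} outside [0,1]")
        if not self.allow_multi_category and sum(prev.values()) > 1.0:
            raise ValueError(
                "single-episode mode requires prevalences summing to <= 1"
            )
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        names = [a.name for a in self.analyte_panel]
        if len(set(names)) != len(names):
            raise ValueError("duplicate analyte names in panel")


@dataclass
class SyntheticCohort:
    """The six relational tables plus ground truth.

    ``ground_truth`` records every injected event (case, category, time, BG
    value); the prediction pipeline must never read it outside of tests.
    """

    demographics: pd.DataFrame
    admissions: pd.DataFrame
    lab: pd.DataFrame
    drug: pd.DataFrame
    diagnosis: pd.DataFrame
    icu: pd.DataFrame
    ground_truth: pd.DataFrame

    _TABLES = ("demographics", "admissions", "lab", "drug", "diagnosis",
               "icu", "ground_truth")
    _TIME_COLS = {
        "admissions": ["admit_time", "discharge_time"],
        "lab": ["time"],
        "drug": ["time"],
        "diagnosis": ["time"],
        "icu": ["icu_start", "icu_end"],
        "ground_truth": ["event_time"],
    }

    def write(self, outdir: str | Path) -> None:
        """Write all tables as UTF-8 CSV with ISO-8601 timestamps."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df = getattr(self, name)
            df.to_csv(outdir / f"{name}.csv", index=False,
                      date_format="%Y-%m-%dT%H:%M:%S")

    @classmethod
    def read(cls, indir: str | Path) -> "SyntheticCohort":
        indir = Path(indir)
        tables = {}
        for name in cls._TABLES:
            df = pd.read_csv(indir / f"{name}.csv")
            for col in cls._TIME_COLS.get(name, []):
                df[col] = pd.to_datetime(df[col])
            tables[name] = df
        return cls(**tables)


def _empty_cohort() -> SyntheticCohort:
    ts = "datetime64[ns]"
    return SyntheticCohort(
        demographics=pd.DataFrame({
            "patient_id": pd.Series(dtype=str), "age": pd.Series(dtype=float),
            "sex": pd.Series(dtype=str), "height_cm": pd.Series(dtype=float),
            "weight_kg": pd.Series(dtype=float),
            "language": pd.Series(dtype=str),
            "civil_status": pd.Series(dtype=str)}),
        admissions=pd.DataFrame({
            "case_id": pd.Series(dtype=str), "patient_id": pd.Series(dtype=str),
            "admit_time": pd.Series(dtype=ts),
            "discharge_time": pd.Series(dtype=ts)}),
        lab=pd.DataFrame({
            "case_id": pd.Series(dtype=str), "analyte": pd.Series(dtype=str),
            "value": pd.Series(dtype=float), "time": pd.Series(dtype=ts)}),
        drug=pd.DataFrame({
            "case_id": pd.Series(dtype=str), "atc_code": pd.Series(dtype=str),
            "time": pd.Series(dtype=ts), "pre_admission": pd.Series(dtype=int)}),
        diagnosis=pd.DataFrame({
            "patient_id": pd.Series(dtype=str),
            "icd10_code": pd.Series(dtype=str), "time": pd.Series(dtype=ts)}),
        icu=pd.DataFrame({
            "case_id": pd.Series(dtype=str), "icu_start": pd.Series(dtype=ts),
            "icu_end": pd.Series(dtype=ts)}),
        ground_truth=pd.DataFrame({
            "case_id": pd.Series(dtype=str), "category": pd.Series(dtype=int),
            "event_time": pd.Series(dtype=ts),
            "bg_value": pd.Series(dtype=float)}),
    )


def _intensity(hour_of_day: np.ndarray) -> np.ndarray:
    """Daytime-peaked sampling intensity multiplier, mean 1 over the day."""
    return np.where((hour_of_day >= 7.0) & (hour_of_day < 19.0), 1.6, 0.4)


_INTENSITY_MAX = 1.6


def _to_seconds_timedelta(hours: np.ndarray) -> pd.TimedeltaIndex:
    # whole-second resolution so that CSV round trips are lossless
    return pd.to_timedelta(np.round(np.asarray(hours) * 3600.0).astype(np.int64),
                           unit="s")


def _draw_event_value(category: int, rng: np.random.Generator) -> float:
    lo, hi = EVENT_VALUE_RANGES[int(category)]
    return float(rng.uniform(lo, hi))


def _ou_series(times: np.ndarray, setpoint: float, rng: np.random.Generator,
               sigma: float = 0.7, tau: float = 8.0) -> np.ndarray:
    """Ornstein-Uhlenbeck sampled at irregular times (hours)."""
    n = len(times)
    out = np.empty(n)
    x = setpoint + sigma * rng.standard_normal()
    prev_t = times[0] if n else 0.0
    for i in range(n):
        dt = times[i] - prev_t
        a = np.exp(-dt / tau)
        x = setpoint + (x - setpoint) * a + sigma * np.sqrt(
            max(0.0, 1.0 - a * a)) * rng.standard_normal()
        out[i] = x
        prev_t = times[i]
    return out


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort. Byte-identical for a fixed seed."""
    config.validate()
    if config.n_patients == 0:
        return _empty_cohort()
    rng = np.random.default_rng(config.seed)
    panel = config.analyte_panel
    n_analyte = len(panel)
    a_names = np.array([a.name for a in panel])
    a_mean = np.array([a.mean for a in panel])
    a_sd = np.array([a.sd for a in panel])
    a_rate = np.array([a.rate_per_day for a in panel])
    glucose_idx = int(np.where(a_names == "glucose")[0][0]) \
        if "glucose" in a_names else -1
    if glucose_idx < 0:
        raise ValueError("panel must contain a 'glucose' analyte")

    # ---- patients ---------------------------------------------------------
    n_pat = config.n_patients
    patient_ids = np.array([f"P{i:06d}" for i in range(n_pat)])
    sex = rng.choice(["M", "F"], size=n_pat, p=[0.56, 0.44])
    age = np.clip(rng.normal(64.0, 17.0, n_pat), 18, 98).round(0)
    height = np.where(sex == "M", rng.normal(175.0, 7.0, n_pat),
                      rng.normal(164.0, 7.0, n_pat)).round(0)
    weight = np.exp(rng.normal(np.log(78.0), 0.22, n_pat)).round(1)
    language = rng.choice(_LANGUAGES, size=n_pat, p=[0.62, 0.2, 0.08, 0.10])
    civil = rng.choice(_CIVIL, size=n_pat, p=[0.25, 0.5, 0.13, 0.12])

    # deliberately implausible demographic entries (data-entry errors)
    for arr, bad in ((age, (150.0, 15.0, 212.0)),
                     (height, (260.0, 85.0)),
                     (weight, (500.0, 18.0))):
        mask = rng.random(n_pat) < config.corruption_prob
        arr[mask] = rng.choice(bad, size=int(mask.sum()))

    demographics = pd.DataFrame({
        "patient_id": patient_ids, "age": age, "sex": sex,
        "height_cm": height, "weight_kg": weight,
        "language": language, "civil_status": civil})

    # ---- admissions -------------------------------------------------------
    n_adm = 1 + rng.poisson(config.extra_admissions_mean, n_pat)
    case_patient_idx = np.repeat(np.arange(n_pat), n_adm)
    n_case = len(case_patient_idx)
    case_ids = np.array([f"C{i:07d}" for i in range(n_case)])
    admit_offset_h = rng.uniform(0, 730 * 24, n_case)
    admit_time = BASE_TIME + _to_seconds_timedelta(admit_offset_h)

    course_h = np.maximum(
        config.min_course_hours,
        np.exp(rng.normal(np.log(config.los_median_days * 24.0),
                          config.los_sigma, n_case)))

    # ---- event categories -------------------------------------------------
    prev = dict(config.category_prevalences)
    cats = np.array(sorted(prev))
    if config.allow_multi_category:
        event_mask = rng.random((n_case, len(cats))) < np.array(
            [prev[c] for c in cats])
        events_per_case = [cats[event_mask[i]] for i in range(n_case)]
    else:
        p = np.array([prev[c] for c in cats])
        draw = rng.choice(np.append(cats, 0), size=n_case,
                          p=np.append(p, 1.0 - p.sum()))
        events_per_case = [np.array([d]) if d else np.array([], dtype=int)
                           for d in draw]

    has_event = np.array([len(e) > 0 for e in events_per_case])
    recovery_h = np.where(
        has_event,
        np.exp(rng.normal(np.log(config.recovery_median_days * 24.0),
                          config.recovery_sigma, n_case)),
        0.0)
    los_h = course_h + recovery_h

    # event times: the (last) event terminates the baseline course; in
    # multi-category mode earlier categories are spread over the later part
    # of the course.
    event_rows: list[tuple[int, int, float]] = []  # (case idx, category, hours)
    for i, evs in enumerate(events_per_case):
        if len(evs) == 0:
            continue
        evs = rng.permutation(evs)
        if len(evs) == 1:
            times = np.array([course_h[i]])
        else:
            earlier = np.sort(rng.uniform(0.55, 0.95, len(evs) - 1)) * course_h[i]
            times = np.append(earlier, course_h[i])
        for c, t in zip(evs, times):
            event_rows.append((i, int(c), float(t)))

    discharge_time = admit_time + _to_seconds_timedelta(los_h)
    admissions = pd.DataFrame({
        "case_id": case_ids, "patient_id": patient_ids[case_patient_idx],
        "admit_time": admit_time, "discharge_time": discharge_time})

    # ---- laboratory sampling times ---------------------------------------
    include = rng.random((n_case, n_analyte)) < config.analyte_inclusion_prob
    include[:, glucose_idx] = True
    lam = (a_rate[None, :] / 24.0) * los_h[:, None] * _INTENSITY_MAX
    counts = rng.poisson(np.where(include, lam, 0.0))
    row_case = np.repeat(np.arange(n_case * n_analyte) // n_analyte,
                         counts.ravel())
    row_analyte = np.repeat(np.tile(np.arange(n_analyte), n_case),
                            counts.ravel())
    t = rng.uniform(0.0, los_h[row_case])
    hod = (admit_offset_h[row_case] + t) % 24.0
    keep = rng.random(len(t)) < _intensity(hod) / _INTENSITY_MAX
    row_case, row_analyte, t = row_case[keep], row_analyte[keep], t[keep]

    # forced admission glucose draw: guarantees an early predictor datum
    t0 = rng.uniform(0.2, 1.0, n_case)
    row_case = np.append(row_case, np.arange(n_case))
    row_analyte = np.append(row_analyte, np.full(n_case, glucose_idx))
    t = np.append(t, t0)
    t = np.round(t * 3600.0) / 3600.0  # whole seconds

    order = np.lexsort((row_analyte, t, row_case))
    row_case, row_analyte, t = row_case[order], row_analyte[order], t[order]

    # ---- values -----------------------------------------------------------
    values = a_mean[row_analyte] + a_sd[row_analyte] * rng.standard_normal(
        len(t))

    # per-case event lookup arrays (single-episode fast path; multi-category
    # cohorts iterate per event)
    sig_names = list(config.signal_signature)
    sign_mat = np.zeros((n_analyte, 5))
    for name, per_cat in config.signal_signature.items():
        if name not in a_names:
            raise ValueError(f"signal analyte {name!r} not in panel")
        ai = int(np.where(a_names == name)[0][0])
        for c, s in per_cat.items():
            sign_mat[ai, int(c)] = float(s)

    W = config.signal_window_hours
    strength = config.signal_strength
    case_bounds = np.searchsorted(row_case, np.arange(n_case + 1))
    if strength > 0 and event_rows:
        for ci, cat, te in event_rows:
            lo, hi = case_bounds[ci], case_bounds[ci + 1]
            if hi <= lo:
                continue
            ramp = np.clip(1.0 - np.abs(te - t[lo:hi]) / W, 0.0, 1.0)
            shift = (sign_mat[row_analyte[lo:hi], cat] * strength
                     * a_sd[row_analyte[lo:hi]] * ramp)
            values[lo:hi] = values[lo:hi] + shift

    # ---- glucose: OU around a per-case set-point, clipped to safe band ----
    setpoints = rng.normal(6.3, 0.5, n_case)
    gmask = row_analyte == glucose_idx
    g_case = row_case[gmask]
    g_t = t[gmask]
    g_vals = np.empty(gmask.sum())
    # rows are sorted by case then time, so per-case slices are contiguous
    bounds = np.searchsorted(g_case, np.arange(n_case + 1))
    for ci in range(n_case):
        lo, hi = bounds[ci], bounds[ci + 1]
        if hi > lo:
            g_vals[lo:hi] = _ou_series(g_t[lo:hi], setpoints[ci], rng)
    # pre-event drift toward the relevant band edge (part of the signal)
    if strength > 0 and event_rows:
        edge = {1: GLUCOSE_SAFE_BAND[0], 2: GLUCOSE_SAFE_BAND[1],
                3: GLUCOSE_SAFE_BAND[1], 4: GLUCOSE_SAFE_BAND[1]}
        frac = min(strength, 1.5) / 1.5
        for ci, cat, te in event_rows:
            lo, hi = bounds[ci], bounds[ci + 1]
            if hi <= lo:
                continue
            ramp = np.clip(1.0 - np.abs(te - g_t[lo:hi]) / W, 0.0, 1.0)
            g_vals[lo:hi] += (edge[cat] - setpoints[ci]) * ramp * frac
    g_vals = np.clip(g_vals, *GLUCOSE_SAFE_BAND)
    values[gmask] = g_vals

    # ---- corruption of laboratory rows ------------------------------------
    hard_bad = {"chloride": (40.0, 160.0), "potassium": (0.5, 12.0),
                "sodium": (80.0, 220.0), "ph": (6.0, 8.4)}
    for name, (lo_v, hi_v) in hard_bad.items():
        sel = np.flatnonzero(a_names[row_analyte] == name)
        bad = sel[rng.random(len(sel)) < config.corruption_prob]
        values[bad] = np.where(rng.random(len(bad)) < 0.5, lo_v, hi_v)
    negok = a_names[row_analyte] == "base_excess"
    candidates = np.flatnonzero(~gmask & ~negok)
    bad = candidates[rng.random(len(candidates)) < config.corruption_prob / 2]
    values[bad] = -np.abs(values[bad]) - 0.1

    lab = pd.DataFrame({
        "case_id": case_ids[row_case],
        "analyte": a_names[row_analyte],
        "value": values,
        "time": admit_time.values[row_case] + _to_seconds_timedelta(t),
    })

    # ---- injected event measurements --------------------------------------
    gt_case, gt_cat, gt_time, gt_val = [], [], [], []
    ev_rows = []
    for ci, cat, te in event_rows:
        v = _draw_event_value(cat, rng)
        ts = admit_time[ci] + _to_seconds_timedelta(np.array([te]))[0]
        ev_rows.append((case_ids[ci], "glucose", v, ts))
        gt_case.append(case_ids[ci])
        gt_cat.append(cat)
        gt_time.append(ts)
        gt_val.append(v)
    if ev_rows:
        lab = pd.concat(
            [lab, pd.DataFrame(ev_rows, columns=lab.columns)],
            ignore_index=True)
    lab = lab.sort_values(["case_id", "time", "analyte"],
                          kind="stable").reset_index(drop=True)

    ground_truth = pd.DataFrame({
        "case_id": gt_case,
        "category": pd.Series(gt_cat, dtype=int),
        "event_time": pd.Series(gt_time, dtype="datetime64[ns]"),
        "bg_value": pd.Series(gt_val, dtype=float)})
    ground_truth = ground_truth.sort_values(
        ["case_id", "category"], kind="stable").reset_index(drop=True)

    # ---- drugs -------------------------------------------------------------
    d_case, d_atc, d_time, d_pre = [], [], [], []
    pre_add = rng.random(n_case) < 0.30
    n_pre = rng.integers(1, 4, n_case)
    n_stay = rng.poisson(2.0, n_case)
    for ci in range(n_case):
        if pre_add[ci]:
            for _ in range(n_pre[ci]):
                d_case.append(case_ids[ci])
                d_atc.append(rng.choice(_ANTIDIABETIC_ATC))
                d_time.append(admit_time[ci] - pd.Timedelta(
                    seconds=int(rng.uniform(1, 90) * 86400)))
                d_pre.append(1)
        for _ in range(n_stay[ci]):
            pool = _ANTIDIABETIC_ATC if rng.random() < 0.25 else _OTHER_ATC
            d_case.append(case_ids[ci])
            d_atc.append(rng.choice(pool))
            d_time.append(admit_time[ci] + pd.Timedelta(
                seconds=int(rng.uniform(0, los_h[ci]) * 3600)))
            d_pre.append(0)
    drug = pd.DataFrame({"case_id": d_case, "atc_code": d_atc,
                         "time": pd.Series(d_time, dtype="datetime64[ns]"),
                         "pre_admission": pd.Series(d_pre, dtype=int)})

    # ---- diagnoses ---------------------------------------------------------
    dx_pat, dx_code, dx_time = [], [], []
    has_dm = rng.random(n_pat) < 0.35
    n_other = rng.poisson(2.0, n_pat)
    first_admit = pd.Series(admit_time).groupby(case_patient_idx).min()
    for pi in range(n_pat):
        t_dx = first_admit.get(pi, BASE_TIME) - pd.Timedelta(
            seconds=int(rng.uniform(0, 365) * 86400))
        if has_dm[pi]:
            dx_pat.append(patient_ids[pi])
            dx_code.append(rng.choice(_DIABETES_ICD))
            dx_time.append(t_dx)
        for _ in range(n_other[pi]):
            dx_pat.append(patient_ids[pi])
            dx_code.append(rng.choice(_OTHER_ICD))
            dx_time.append(t_dx)
    diagnosis = pd.DataFrame({
        "patient_id": dx_pat, "icd10_code": dx_code,
        "time": pd.Series(dx_time, dtype="datetime64[ns]")})

    # ---- ICU ---------------------------------------------------------------
    in_icu = rng.random(n_case) < config.icu_prob
    i_case, i_start, i_end = [], [], []
    for ci in np.flatnonzero(in_icu):
        a = rng.uniform(0.0, 0.5) * los_h[ci]
        b = a + rng.uniform(0.1, 0.5) * los_h[ci]
        i_case.append(case_ids[ci])
        i_start.append(admit_time[ci] + pd.Timedelta(seconds=int(a * 3600)))
        i_end.append(admit_time[ci] + pd.Timedelta(
            seconds=int(min(b, los_h[ci]) * 3600)))
    icu = pd.DataFrame({"case_id": i_case,
                        "icu_start": pd.Series(i_start, dtype="datetime64[ns]"),
                        "icu_end": pd.Series(i_end, dtype="datetime64[ns]")})

    return SyntheticCohort(demographics, admissions, lab, drug, diagnosis,
                           icu, ground_truth)


def inject_event(case_labs: pd.DataFrame, admit_time: pd.Timestamp,
                 discharge_time: pd.Timestamp, category: int,
                 time_hours: float, rng: np.random.Generator | int = 0,
                 ) -> tuple[pd.DataFrame, float]:
    """Insert a decompensation BG measurement into one case's lab table.

    Returns the modified lab table and the injected BG value. Raises if the
    time lies outside the admission interval or no earlier predictor datum
    exists (an event at or before the first measurement could never be
    predicted and is excluded from modeling by contract).
    """
    if category not in EVENT_VALUE_RANGES:
        raise ValueError(f"category must be in 1..4, got {category}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    los_h = (discharge_time - admit_time) / pd.Timedelta(hours=1)
    if not 0.0 < time_hours <= los_h:
        raise ValueError(
            f"event time {time_hours} h outside admission (0, {los_h:.1f}] h")
    ts = admit_time + _to_seconds_timedelta(np.array([time_hours]))[0]
    if case_labs.empty or not (case_labs["time"] < ts).any():
        raise ValueError("no predictor datum precedes the event time")
    value = _draw_event_value(category, rng)
    row = pd.DataFrame({
        "case_id": [case_labs["case_id"].iloc[0]],
        "analyte": ["glucose"], "value": [value], "time": [ts]})
    out = pd.concat([case_labs, row], ignore_index=True)
    out = out.sort_values(["time", "analyte"], kind="stable").reset_index(
        drop=True)
    return out, value
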