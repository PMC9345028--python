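"""Plausibility cleaning and isolation-based outlier flagging.

Demographic values outside reasonable physiological limits are set to
missing (other fields of the same patient are retained). Laboratory rows
with negative values (except base excess) or values incompatible with life
for chloride, plasma pH, potassium and sodium are removed. Remaining
putative outliers are flagged — not removed — with an Isolation Forest; the
binary flags travel downstream as additional predictor variables marking
potentially severe cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.ensemble import IsolationForest

__all__ = ["PlausibilityLimits", "apply_demographic_limits",
           "apply_lab_limits", "flag_outliers"]


@dataclass(frozen=True)
class PlausibilityLimits:
    """Bounds for cleaning; defaults are the pipeline's clinical limits."""

    #: demographic (lower, upper); out-of-range values become missing
    demographic: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "age": (18.0, 130.0),
            "height_cm": (100.0, 250.0),
            "weight_kg": (25.0, 400.0),
        })
    #: per-analyte hard-removal bounds; rows strictly outside are dropped
    lab_removal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "chloride": (65.0, 138.0),
            "ph": (6.8, 7.8),
            "potassium": (1.3, 9.0),
            "sodium": (100.0, 191.0),
        })
    #: analytes for which negative values are physiological
    allow_negative: frozenset[str] = frozenset({"base_excess"})

    def __post_init__(self) -> None:
        for table in (self.demographic, self.lab_removal):
            for key, (lo, hi) in table.items():
                if not lo < hi:
                    raise ValueError(f"invalid bounds for {key}: ({lo}, {hi})")


def apply_demographic_limits(demographics: pd.DataFrame,
                             limits: PlausibilityLimits | None = None,
                             ) -> pd.DataFrame:
    """Replace out-of-range age/height/weight with NaN; keep everything else."""
    limits = limits or PlausibilityLimits()
    out = demographics.copy()
    for col, (lo, hi) in limits.demographic.items():
        if col not in out.columns:
            continue
        vals = pd.to_numeric(out[col], errors="coerce")
        out[col] = vals.where((vals >= lo) & (vals <= hi))
    return out


def apply_lab_limits(lab: pd.DataFrame,
                     limits: PlausibilityLimits | None = None,
                     ) -> pd.DataFrame:
    """Drop implausible laboratory rows.

    Removes negative values (except for analytes in ``allow_negative``) and
    rows outside the hard-removal bounds for the analytes that have them.
    All other analytes are untouched. Idempotent.
    """
    limits = limits or PlausibilityLimits()
    value = lab["value"]
    keep = value.notna()
    negok = lab["analyte"].isin(limits.allow_negative)
    keep &= (value >= 0) | negok
    for analyte, (lo, hi) in limits.lab_removal.items():
        here = lab["analyte"] == analyte
        keep &= ~here | ((value >= lo) & (value <= hi))
    return lab.loc[keep].reset_index(drop=True)


def flag_outliers(lab: pd.DataFrame, admissions: pd.DataFrame,
                  contamination: float = 0.01, seed: int = 0,
                  n_estimators: int = 100, min_group: int = 20,
                  fit_mask: pd.Series | None = None) -> pd.Series:
    """Per-measurement binary outlier flags from per-analyte Isolation Forests.

    Each analyte is scored separately on (value, hours since admission)
    pairs, avoiding any imputation across the sparse panel. Returns an int
    Series aligned with ``lab``'s index (1 = flagged). Deterministic for a
    fixed seed; analytes with fewer than ``min_group`` fitting measurements
    are never flagged. Measurement values are never altered.

    ``fit_mask`` restricts the rows the forests are FITTED on (all rows are
    still scored). The pipeline passes the union of look-back windows here
    so that data recorded after a case's decompensation event can never
    influence the flags of earlier measurements.
    """
    flags = pd.Series(0, index=lab.index, dtype=int, name="outlier_flag")
    if lab.empty:
        return flags
    admit = admissions.set_index("case_id")["admit_time"]
    hours = ((lab["time"] - lab["case_id"].map(admit))
             / pd.Timedelta(hours=1)).to_numpy()
    values = lab["value"].to_numpy(dtype=float)
    fit_ok = (np.ones(len(lab), dtype=bool) if fit_mask is None
              else fit_mask.reindex(lab.index).fillna(False).to_numpy())
    for analyte, pos in sorted(lab.groupby("analyte").indices.items()):
        fit_pos = pos[fit_ok[pos]]
        if len(fit_pos) < min_group:
            continue
        forest = IsolationForest(n_estimators=n_estimators,
                                 contamination=contamination,
                                 random_state=seed)
        forest.fit(np.column_stack([values[fit_pos], hours[fit_pos]]))
        pred = forest.predict(np.column_stack([values[pos], hours[pos]]))
        flags.iloc[pos] = (pred == -1).astype(int)
    return flags
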