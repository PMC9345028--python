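"""Confusion matrices, per-class metrics, binary reduction and CV summaries.

All percentages are computed one-vs-rest from confusion-matrix counts:
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), precision = TP/(TP+FP),
balanced accuracy = (sensitivity + specificity)/2. Metrics with a zero
denominator are reported as missing. Display rounding is half-up at the
report's stated precision; raw values are retained internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix", "ClassMetrics", "GROUP_3CLASS", "ratio_percent",
    "confusion", "class_metrics", "binary_reduction", "binary_metrics",
    "cross_validate", "horizon_summary", "importance_report",
]

log = logging.getLogger(__name__)

#: Grouping used for the 3-class (control / hypo / hyper) reports; applied
#: AFTER multiclass decoding.
GROUP_3CLASS: Mapping[int, int] = {0: 0, 1: 1, 2: 2, 3: 2, 4: 2}


def ratio_percent(numerator: float, denominator: float,
                  decimals: int = 2) -> float:
    """Percentage of a count ratio, rounded half-up to ``decimals``."""
    if denominator == 0:
        return float("nan")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConfusionMatrix:
    """Counts by (true, predicted) class with row-relative percentages."""

    counts: pd.DataFrame  # index = true labels, columns = predicted

    @property
    def labels(self) -> list:
        return list(self.counts.index)

    @property
    def row_percent(self) -> pd.DataFrame:
        totals = self.counts.sum(axis=1)
        return self.counts.div(totals.replace(0, np.nan), axis=0) * 100

    def ovr_counts(self, cls) -> tuple[int, int, int, int]:
        """(TP, FP, FN, TN) for one-vs-rest evaluation of ``cls``."""
        c = self.counts
        tp = int(c.loc[cls, cls])
        fp = int(c[cls].sum() - tp)
        fn = int(c.loc[cls].sum() - tp)
        tn = int(c.to_numpy().sum() - tp - fp - fn)
        return tp, fp, fn, tn


@dataclass
class ClassMetrics:
    """One-vs-rest percentages for a single class (NaN where undefined)."""

    cls: object
    sensitivity: float
    specificity: float
    precision: float
    balanced_accuracy: float

    def rounded(self, decimals: int = 1) -> dict[str, float]:
        out = {}
        for name in ("sensitivity", "specificity", "precision",
                     "balanced_accuracy"):
            v = getattr(self, name)
            out[name] = (float("nan") if np.isnan(v)
                         else ratio_percent(v, 100.0, decimals))
        return out


def confusion(y_true: Sequence, y_pred: Sequence,
              labels: Sequence | None = None,
              grouping: Mapping | None = None) -> ConfusionMatrix:
    """Confusion matrix; an optional grouping map is applied to both axes."""
    y_true = pd.Series(list(y_true))
    y_pred = pd.Series(list(y_pred))
    if len(y_true) != len(y_pred):
        raise ValueError("label vectors must have equal length")
    if grouping is not None:
        present = set(y_true) | set(y_pred)
        missing = {v for v in present if v not in grouping}
        if missing:
            raise ValueError(f"labels not covered by grouping: {missing}")
        y_true = y_true.map(grouping)
        y_pred = y_pred.map(grouping)
    if labels is None:
        labels = sorted(set(y_true) | set(y_pred))
    else:
        unknown = (set(y_true) | set(y_pred)) - set(labels)
        if unknown:
            raise ValueError(f"unknown labels: {sorted(unknown)}")
    counts = pd.crosstab(y_true, y_pred).reindex(
        index=labels, columns=labels, fill_value=0)
    counts.index.name = "true"
    counts.columns.name = "predicted"
    return ConfusionMatrix(counts.astype(int))


def class_metrics(cm: ConfusionMatrix, cls) -> ClassMetrics:
    """One-vs-rest metrics (as percentages) for one class of a matrix."""
    tp, fp, fn, tn = cm.ovr_counts(cls)
    sens = 100.0 * tp / (tp + fn) if tp + fn else np.nan
    spec = 100.0 * tn / (tn + fp) if tn + fp else np.nan
    prec = 100.0 * tp / (tp + fp) if tp + fp else np.nan
    bacc = (sens + spec) / 2.0
    return ClassMetrics(cls, sens, spec, prec, bacc)


def binary_reduction(labels: Sequence) -> np.ndarray:
    """Collapse 5-class labels to decompensated (1) vs nondecompensated (0)."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() > 4:
        raise ValueError("labels must be in 0..4")
    return (labels != 0).astype(int)


def binary_metrics(y_true: Sequence, y_pred: Sequence) -> ClassMetrics:
    """Metrics of the multiclass classifier reduced to a binary one."""
    cm = confusion(binary_reduction(y_true), binary_reduction(y_pred),
                   labels=[0, 1])
    return class_metrics(cm, 1)


def cross_validate(features: pd.DataFrame,
                   fit_predict: Callable[[pd.DataFrame, pd.DataFrame],
                                         np.ndarray],
                   k: int = 5, seed: int = 0,
                   grouping: Mapping | None = GROUP_3CLASS,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Case-level k-fold cross-validation of a train->predict pipeline.

    ``fit_predict(train_features, test_features)`` must return predicted
    classes for the test rows. Folds lacking any class in their training
    portion are skipped with a warning. Returns (per-fold metrics,
    mean/SD summary); metric columns are ``<metric>_<class>`` percentages.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    cases = np.unique(features["case_id"])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(cases)
    folds = np.array_split(perm, k)
    classes = sorted(set(
        grouping[t] for t in features["target"].unique()
    )) if grouping else sorted(features["target"].unique())
    rows = []
    for i, fold_cases in enumerate(folds):
        te = features["case_id"].isin(fold_cases)
        train, test = features.loc[~te], features.loc[te]
        if (set(train["target"].unique()) != set(features["target"].unique())
                or test.empty):
            log.warning("fold %d skipped: missing class or empty test", i)
            continue
        pred = fit_predict(train.reset_index(drop=True),
                           test.reset_index(drop=True))
        cm = confusion(test["target"].to_numpy(), pred, grouping=grouping,
                       labels=classes)
        row = {"fold": i}
        for cls in classes:
            m = class_metrics(cm, cls)
            row[f"sensitivity_{cls}"] = m.sensitivity
            row[f"specificity_{cls}"] = m.specificity
            row[f"precision_{cls}"] = m.precision
            row[f"balanced_accuracy_{cls}"] = m.balanced_accuracy
        b = binary_metrics(test["target"].to_numpy(), pred)
        row["binary_sensitivity"] = b.sensitivity
        row["binary_specificity"] = b.specificity
        row["binary_precision"] = b.precision
        rows.append(row)
    per_fold = pd.DataFrame(rows)
    if per_fold.empty:
        raise ValueError("all folds were skipped")
    metric_cols = [c for c in per_fold.columns if c != "fold"]
    summary = pd.DataFrame({"mean": per_fold[metric_cols].mean(),
                            "sd": per_fold[metric_cols].std(ddof=1)})
    return per_fold, summary


def horizon_summary(manifest: pd.DataFrame) -> pd.DataFrame:
    """Median and IQR of look-back length (days) and horizon (hours).

    One row per category present in the manifest; control instances have no
    horizon. Categories without instances are simply absent.
    """
    rows = []
    for cat, grp in manifest.groupby("category"):
        look_days = (grp["window_end"] - grp["window_start"]) / 24.0
        row = {"category": int(cat),
               "lookback_days_median": float(look_days.median()),
               "lookback_days_q1": float(look_days.quantile(0.25)),
               "lookback_days_q3": float(look_days.quantile(0.75))}
        hz = grp["horizon_hours"].dropna()
        row["horizon_hours_median"] = float(hz.median()) if len(hz) else np.nan
        row["horizon_hours_q1"] = float(hz.quantile(0.25)) if len(hz) else np.nan
        row["horizon_hours_q3"] = float(hz.quantile(0.75)) if len(hz) else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def importance_report(ensemble, top_k: int = 10
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Top-k variables per ensemble member, and their union across members."""
    cols = {}
    union: list[str] = []
    for m in ensemble.models:
        top = m.importance.sort_values(ascending=False).head(top_k)
        cols[m.label] = list(top.index)
        for name in top.index:
            if name not in union:
                union.append(name)
    report = pd.DataFrame(cols)
    report.index.name = "rank"
    return report, union
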