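"""Gradient-boosted binary classifiers for decompensation-category sets.

Each binary model type detects a clinically relevant combination of BG
decompensation categories (its positive set, a subset of {1,2,3,4});
instances from cases with no category in the positive set serve as
controls — including, e.g., hyperglycemic cases acting as controls for a
hypoglycemia model. Training uses sparsity-aware extreme gradient boosting
(missing feature values take a learned default direction at each node),
inverse-class-frequency instance weights, a case-level 70/30 split, and a
stochastic search over the hyperparameter grid scored on the withheld 30%.
Precision, sensitivity, AUC ROC and informedness (Youden's J) of the
retained model are recorded, along with gain-based feature importance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from xgboost import XGBClassifier

from .features import feature_columns

__all__ = [
    "BinaryModelSpec", "TrainedBinaryModel", "DEFAULT_POSITIVE_SETS",
    "DEFAULT_SEARCH_SPACE", "enumerate_candidate_specs", "make_instances",
    "split_cases", "train_binary", "importance",
]

log = logging.getLogger(__name__)

#: Default library of binary model types. A, B, G, H, I are the combinations
#: that form the reference ensemble (all decompensations; hypoglycemia only;
#: hypoglycemia + severe hyperglycemia; all hyperglycemia; moderate + severe
#: hyperglycemia); C-F complete the library and are configurable.
DEFAULT_POSITIVE_SETS: Mapping[str, frozenset[int]] = {
    "A": frozenset({1, 2, 3, 4}),
    "B": frozenset({1}),
    "C": frozenset({2}),
    "D": frozenset({3}),
    "E": frozenset({4}),
    "F": frozenset({1, 3, 4}),
    "G": frozenset({1, 4}),
    "H": frozenset({2, 3, 4}),
    "I": frozenset({3, 4}),
}

#: Stochastic-search distributions: lists are sampled uniformly, tuples
#: (lo, hi) uniformly on a log scale.
DEFAULT_SEARCH_SPACE: Mapping[str, object] = {
    "max_depth": [2, 3, 4, 5, 6],
    "learning_rate": (0.02, 0.3),
    "n_estimators": [60, 100, 150, 200, 250],
    "subsample": [0.6, 0.8, 1.0],
    "colsample_bytree": [0.5, 0.7, 1.0],
    "min_child_weight": [1, 3, 5, 10],
    "reg_lambda": (0.1, 10.0),
    "gamma": [0.0, 0.1, 0.5],
}


@dataclass(frozen=True)
class BinaryModelSpec:
    """A labeled positive-class combination plus its search configuration."""

    label: str
    positive_set: frozenset[int]
    search_space: Mapping[str, object] = field(
        default_factory=lambda: dict(DEFAULT_SEARCH_SPACE))
    budget: int = 100

    def __post_init__(self) -> None:
        if not self.positive_set:
            raise ValueError(f"model {self.label}: empty positive set")
        if not self.positive_set <= {1, 2, 3, 4}:
            raise ValueError(
                f"model {self.label}: positive set must be within {{1,2,3,4}}")


def enumerate_candidate_specs(
    positive_sets: Mapping[str, Sequence[int]] | None = None,
    budget: int = 100,
    search_space: Mapping[str, object] | None = None,
) -> list[BinaryModelSpec]:
    """The candidate binary-model library (default: the 9 types A-I)."""
    sets = positive_sets or DEFAULT_POSITIVE_SETS
    seen: dict[frozenset[int], str] = {}
    specs = []
    for label, pos in sets.items():
        pos = frozenset(int(c) for c in pos)
        if pos in seen:
            raise ValueError(
                f"duplicate positive set for {label!r} and {seen[pos]!r}")
        seen[pos] = label
        specs.append(BinaryModelSpec(
            label, pos, dict(search_space or DEFAULT_SEARCH_SPACE), budget))
    return specs


def make_instances(features: pd.DataFrame, spec: BinaryModelSpec
                   ) -> tuple[pd.DataFrame, np.ndarray, np.ndarray,
                              np.ndarray]:
    """Build (X, y, weights, case_ids) for one binary model.

    Positives are all instances whose target category lies in the positive
    set. Cases without any such category act as controls through a single
    instance: the window of their earliest event if they decompensated in
    categories outside the positive set, or their full-stay window
    otherwise. Class weights are inverse-frequency, normalised to mean 1.
    """
    pos_mask = features["target"].isin(spec.positive_set)
    pos_cases = set(features.loc[pos_mask, "case_id"])
    ctrl = features.loc[~features["case_id"].isin(pos_cases)]
    with_event = ctrl.loc[ctrl["target"] > 0]
    earliest = (with_event.sort_values("window_end_hours", kind="stable")
                .drop_duplicates("case_id", keep="first"))
    no_event = ctrl.loc[(ctrl["target"] == 0)
                        & ~ctrl["case_id"].isin(set(earliest["case_id"]))]
    controls = pd.concat([earliest, no_event])
    data = pd.concat([features.loc[pos_mask], controls])
    y = np.concatenate([np.ones(int(pos_mask.sum()), dtype=int),
                        np.zeros(len(controls), dtype=int)])
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"model {spec.label}: both classes required "
            f"(positives={n_pos}, controls={n_neg})")
    n = len(y)
    w = np.where(y == 1, n / (2.0 * n_pos), n / (2.0 * n_neg))
    X = data[feature_columns(features)].astype(float)
    return (X.reset_index(drop=True), y, w,
            data["case_id"].to_numpy())


def split_cases(case_ids: Sequence[str], ratio: float = 0.7, seed: int = 0,
                patient_of: Mapping[str, str] | None = None,
                ) -> tuple[np.ndarray, np.ndarray]:
    """Case-level (optionally patient-level) train/test partition.

    Exactly ``round(ratio * n_units)`` units go to training; no unit appears
    in both partitions. With ``patient_of`` given, units are patients, so
    repeat admissions never straddle the split.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"split ratio must be in (0, 1), got {ratio}")
    cases = np.unique(np.asarray(case_ids))
    rng = np.random.default_rng(seed)
    if patient_of is not None:
        patients = rng.permutation(np.unique([patient_of[c] for c in cases]))
        n_train = int(np.floor(len(patients) * ratio + 0.5))
        train_pat = set(patients[:n_train])
        in_train = np.array([patient_of[c] in train_pat for c in cases])
        return np.sort(cases[in_train]), np.sort(cases[~in_train])
    perm = rng.permutation(cases)
    n_train = int(np.floor(len(cases) * ratio + 0.5))
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


@dataclass
class TrainedBinaryModel:
    """A retained boosted-tree model with its spec, metrics and importance."""

    spec: BinaryModelSpec
    model: XGBClassifier
    params: dict
    metrics: dict[str, float]
    importance: pd.Series
    feature_names: list[str]
    split_seed: int
    threshold: float = 0.5

    @property
    def label(self) -> str:
        return self.spec.label

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(X[self.feature_names])[:, 1]

    def vote(self, X: pd.DataFrame) -> np.ndarray:
        """0/1 vote at the model's probability threshold."""
        return (self.predict_proba(X) >= self.threshold).astype(int)


def _sample_params(space: Mapping[str, object],
                   rng: np.random.Generator) -> dict:
    params = {}
    for key, spec in space.items():
        if isinstance(spec, tuple):
            lo, hi = spec
            params[key] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        else:
            params[key] = spec[int(rng.integers(len(spec)))]
    return params


def _binary_metrics(y_true: np.ndarray, proba: np.ndarray,
                    threshold: float = 0.5) -> dict[str, float]:
    pred = (proba >= threshold).astype(int)
    tp = int(((pred == 1) & (y_true == 1)).sum())
    fp = int(((pred == 1) & (y_true == 0)).sum())
    fn = int(((pred == 0) & (y_true == 1)).sum())
    tn = int(((pred == 0) & (y_true == 0)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    prec = tp / (tp + fp) if tp + fp else np.nan
    return {
        "auc": float(roc_auc_score(y_true, proba)),
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "informedness": sens + spec - 1.0,
    }


def train_binary(spec: BinaryModelSpec, X: pd.DataFrame, y: np.ndarray,
                 weights: np.ndarray, case_ids: np.ndarray,
                 budget: int | None = None, seed: int = 0,
                 ratio: float = 0.7, selection_metric: str = "auc",
                 threshold: float = 0.5) -> TrainedBinaryModel:
    """Stochastic hyperparameter search; retains the best withheld-split model.

    Every sampled parameter combination is fitted on the 70% training cases
    with inverse-frequency sample weights and scored on the withheld 30%;
    the model maximising ``selection_metric`` is kept together with its
    withheld-split metrics and total-gain feature importance.
    """
    budget = spec.budget if budget is None else budget
    if budget < 1:
        raise ValueError("search budget must be >= 1")
    if len(np.unique(y)) < 2:
        raise ValueError(f"model {spec.label}: y contains a single class")
    rng = np.random.default_rng(seed)
    train_cases, test_cases = split_cases(case_ids, ratio=ratio, seed=seed)
    in_train = np.isin(case_ids, train_cases)
    if len(np.unique(y[in_train])) < 2 or len(np.unique(y[~in_train])) < 2:
        raise ValueError(
            f"model {spec.label}: a split partition lost a class; "
            "use more cases")
    Xtr, Xte = X.loc[in_train], X.loc[~in_train]
    ytr, yte = y[in_train], y[~in_train]
    wtr = weights[in_train]

    best = None
    for k in range(budget):
        params = _sample_params(spec.search_space, rng)
        model = XGBClassifier(
            **params, tree_method="hist", n_jobs=1,
            random_state=int(rng.integers(2 ** 31)),
            eval_metric="logloss", base_score=0.5)
        model.fit(Xtr, ytr, sample_weight=wtr)
        proba = model.predict_proba(Xte)[:, 1]
        metrics = _binary_metrics(yte, proba, threshold)
        score = metrics[selection_metric]
        if best is None or score > best[0]:
            best = (score, model, params, metrics)
        log.debug("model %s candidate %d/%d: %s=%.4f", spec.label, k + 1,
                  budget, selection_metric, score)

    _, model, params, metrics = best
    booster = model.get_booster()
    gain = booster.get_score(importance_type="total_gain")
    imp = pd.Series(gain, dtype=float).reindex(X.columns).fillna(0.0)
    imp.name = f"importance_{spec.label}"
    log.info("model %s (+%s): AUC=%.3f sens=%.3f prec=%.3f J=%.3f",
             spec.label, sorted(spec.positive_set), metrics["auc"],
             metrics["sensitivity"], metrics["precision"],
             metrics["informedness"])
    return TrainedBinaryModel(spec=spec, model=model, params=params,
                              metrics=metrics, importance=imp,
                              feature_names=list(X.columns),
                              split_seed=seed, threshold=threshold)


def importance(model: TrainedBinaryModel, top_k: int | None = None
               ) -> pd.Series:
    """Gain-based variable importance, sorted descending.

    The underlying score is the total loss reduction contributed by splits
    on each variable, aggregated over every tree of the ensemble; variables
    never split on score 0.
    """
    if not isinstance(model, TrainedBinaryModel):
        raise TypeError("importance() requires a trained binary model")
    imp = model.importance.sort_values(ascending=False)
    return imp.head(top_k) if top_k else imp
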