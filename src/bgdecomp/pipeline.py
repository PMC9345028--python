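"""End-to-end orchestration: simulate -> clean -> label -> featurize ->
train binary library -> GA-composed ECOC ensemble -> evaluate.

The canonical experiment splits cases 70/30 at the outer level. Binary
models are trained on the 70% (with their own inner 70/30 case split for
hyperparameter selection), the GA composition fitness is measured on the
inner validation portion, and all reported multiclass metrics come from the
untouched outer 30%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import binary_models as bm
from . import ecoc, evaluation, features, labeling, preprocessing
from .synthetic_cohort import CohortConfig, SyntheticCohort, generate_cohort

__all__ = ["PipelineConfig", "PipelineResult", "prepare_features",
           "train_candidates", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Knobs of the full experiment; defaults give a desk-scale run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    limits: preprocessing.PlausibilityLimits = field(
        default_factory=preprocessing.PlausibilityLimits)
    contamination: float = 0.01
    #: candidate binary model types (subset of labels A-I by default)
    positive_sets: Mapping[str, frozenset[int]] = field(
        default_factory=lambda: dict(bm.DEFAULT_POSITIVE_SETS))
    #: stochastic-search budget per binary model
    budget: int = 100
    selection_metric: str = "auc"
    vote_threshold: float = 0.5
    split_ratio: float = 0.7
    ga: ecoc.GAConfig = field(default_factory=ecoc.GAConfig)
    fitness: str = "macro_precision"
    priority: tuple[int, ...] = ecoc.DEFAULT_TIEBREAK_PRIORITY
    apply_inclusion_criteria: bool = False
    first_measurement: str = "any"


@dataclass
class PipelineResult:
    cohort: SyntheticCohort
    events: pd.DataFrame
    manifest: pd.DataFrame
    features: pd.DataFrame
    encoding: features.CategoryEncoding
    models: list[bm.TrainedBinaryModel]
    ensemble: ecoc.EnsembleSpec
    ga_report: dict
    y_true: np.ndarray
    y_pred: np.ndarray
    metrics: dict


def prepare_features(cohort: SyntheticCohort, config: PipelineConfig,
                     seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame,
                                             pd.DataFrame,
                                             features.CategoryEncoding]:
    """Clean tables, detect events, build windows and derive features.

    Returns (feature table, events, windows manifest, encoding).
    """
    demo = preprocessing.apply_demographic_limits(cohort.demographics,
                                                  config.limits)
    lab = preprocessing.apply_lab_limits(cohort.lab, config.limits)
    events = labeling.detect_events_cohort(
        lab, cohort.admissions, first_measurement=config.first_measurement)
    manifest = labeling.build_windows_manifest(lab, cohort.admissions, events)
    # outlier forests are fitted on look-back rows only, so post-event data
    # can never influence any feature bit
    last_end = manifest.groupby("case_id")["window_end"].max()
    labh = labeling.add_hours(lab, cohort.admissions)
    fit_mask = labh["hours"] < labh["case_id"].map(last_end).fillna(np.inf)
    flags = preprocessing.flag_outliers(lab, cohort.admissions,
                                        contamination=config.contamination,
                                        seed=seed, fit_mask=fit_mask)
    if config.apply_inclusion_criteria:
        keep = _included_cases(cohort, lab)
        manifest = manifest.loc[manifest["case_id"].isin(keep)]
    feats, enc = features.assemble_features(
        manifest, lab=lab, admissions=cohort.admissions, demographics=demo,
        drug=cohort.drug, diagnosis=cohort.diagnosis, icu=cohort.icu,
        events=events, outlier_flags=flags)
    return feats, events, manifest, enc


def _included_cases(cohort: SyntheticCohort, lab: pd.DataFrame) -> set[str]:
    pat_of = cohort.admissions.set_index("case_id")["patient_id"]
    labp = lab.assign(patient_id=lab["case_id"].map(pat_of))
    keep: set[str] = set()
    for pid, cases in cohort.admissions.groupby("patient_id")["case_id"]:
        ok, _ = labeling.meets_inclusion_criteria(
            labp.loc[labp["patient_id"] == pid],
            cohort.diagnosis.loc[cohort.diagnosis["patient_id"] == pid],
            cohort.drug.loc[cohort.drug["case_id"].isin(set(cases))])
        if ok:
            keep.update(cases)
    return keep


def train_candidates(feats: pd.DataFrame, config: PipelineConfig,
                     seed: int = 0, budget: int | None = None,
                     ) -> list[bm.TrainedBinaryModel]:
    """Train the whole binary-model library on one feature table."""
    specs = bm.enumerate_candidate_specs(config.positive_sets,
                                         budget=budget or config.budget)
    models = []
    for j, spec in enumerate(specs):
        X, y, w, cases = bm.make_instances(feats, spec)
        models.append(bm.train_binary(
            spec, X, y, w, cases, seed=seed + 17 * j,
            ratio=config.split_ratio,
            selection_metric=config.selection_metric,
            threshold=config.vote_threshold))
    return models


def run_pipeline(config: PipelineConfig, seed: int = 0,
                 cohort: SyntheticCohort | None = None) -> PipelineResult:
    """The full experiment on a (generated or supplied) cohort."""
    if cohort is None:
        cohort = generate_cohort(config.cohort)
    feats, events, manifest, enc = prepare_features(cohort, config, seed)

    all_cases = feats["case_id"].to_numpy()
    train_cases, test_cases = bm.split_cases(all_cases,
                                             ratio=config.split_ratio,
                                             seed=seed)
    tr = feats.loc[feats["case_id"].isin(train_cases)].reset_index(drop=True)
    te = feats.loc[feats["case_id"].isin(test_cases)].reset_index(drop=True)

    models = train_candidates(tr, config, seed=seed)

    # GA fitness on the inner validation part of the training data: the
    # cases each model withheld during its own split (use the first model's
    # inner split for a shared validation set)
    inner_train, inner_val = bm.split_cases(
        tr["case_id"].to_numpy(), ratio=config.split_ratio, seed=seed)
    val = tr.loc[tr["case_id"].isin(inner_val)].reset_index(drop=True)
    Xval = val[features.feature_columns(val)].astype(float)
    ensemble, report = ecoc.optimize_composition(
        models, Xval, val["target"].to_numpy(), ga=config.ga, seed=seed,
        fitness=config.fitness, priority=config.priority)

    Xte = te[features.feature_columns(te)].astype(float)
    y_true = te["target"].to_numpy()
    y_pred = ensemble.predict(Xte)

    cm3 = evaluation.confusion(y_true, y_pred,
                               grouping=evaluation.GROUP_3CLASS,
                               labels=[0, 1, 2])
    cm5 = evaluation.confusion(y_true, y_pred, labels=[0, 1, 2, 3, 4])
    metrics: dict = {"n_test_instances": len(y_true),
                     "ga_fitness": report["fitness"],
                     "ensemble": report["labels"]}
    for cls, name in ((0, "control"), (1, "hypoglycemia"),
                      (2, "hyperglycemia")):
        m = evaluation.class_metrics(cm3, cls)
        metrics[f"sensitivity_{name}"] = m.sensitivity
        metrics[f"specificity_{name}"] = m.specificity
        metrics[f"precision_{name}"] = m.precision
        metrics[f"balanced_accuracy_{name}"] = m.balanced_accuracy
    b = evaluation.binary_metrics(y_true, y_pred)
    metrics["binary_sensitivity"] = b.sensitivity
    metrics["binary_specificity"] = b.specificity
    metrics["binary_precision"] = b.precision
    metrics["binary_balanced_accuracy"] = b.balanced_accuracy
    metrics["member_auc"] = {m.label: m.metrics["auc"]
                             for m in ensemble.models}
    metrics["confusion_3class"] = cm3.counts
    metrics["confusion_5class"] = cm5.counts

    return PipelineResult(cohort=cohort, events=events, manifest=manifest,
                          features=feats, encoding=enc, models=models,
                          ensemble=ensemble, ga_report=report,
                          y_true=y_true, y_pred=y_pred, metrics=metrics)
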