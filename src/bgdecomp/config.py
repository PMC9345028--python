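"""YAML configuration loading for the pipeline.

Only keys present in the file override defaults; unknown keys raise. See
``PipelineConfig`` and ``CohortConfig`` for the semantics of each setting.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .binary_models import DEFAULT_SEARCH_SPACE
from .ecoc import GAConfig
from .pipeline import PipelineConfig
from .preprocessing import PlausibilityLimits
from .synthetic_cohort import AnalyteSpec, CohortConfig

__all__ = ["load_config", "dump_default_config"]


def _build(cls, data: dict, **overrides):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**{**data, **overrides})


def load_config(path: str | Path | None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file (or defaults)."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "cohort" in data:
        cdata = dict(data.pop("cohort"))
        if "category_prevalences" in cdata:
            cdata["category_prevalences"] = {
                int(k): float(v)
                for k, v in cdata["category_prevalences"].items()}
        if "analyte_panel" in cdata:
            cdata["analyte_panel"] = tuple(
                AnalyteSpec(**a) for a in cdata["analyte_panel"])
        kwargs["cohort"] = _build(CohortConfig, cdata)
    if "limits" in data:
        ldata = dict(data.pop("limits"))
        for key in ("demographic", "lab_removal"):
            if key in ldata:
                ldata[key] = {k: tuple(v) for k, v in ldata[key].items()}
        if "allow_negative" in ldata:
            ldata["allow_negative"] = frozenset(ldata["allow_negative"])
        kwargs["limits"] = _build(PlausibilityLimits, ldata)
    if "ga" in data:
        kwargs["ga"] = _build(GAConfig, dict(data.pop("ga")))
    if "positive_sets" in data:
        kwargs["positive_sets"] = {
            str(k): frozenset(int(c) for c in v)
            for k, v in data.pop("positive_sets").items()}
    if "priority" in data:
        kwargs["priority"] = tuple(int(c) for c in data.pop("priority"))
    return _build(PipelineConfig, data, **kwargs)


def dump_default_config(path: str | Path) -> None:
    """Write a template YAML config with the package defaults."""
    cfg = PipelineConfig()
    doc = {
        "cohort": {
            "n_patients": cfg.cohort.n_patients,
            "extra_admissions_mean": cfg.cohort.extra_admissions_mean,
            "category_prevalences": dict(cfg.cohort.category_prevalences),
            "signal_strength": cfg.cohort.signal_strength,
            "analyte_inclusion_prob": cfg.cohort.analyte_inclusion_prob,
            "allow_multi_category": cfg.cohort.allow_multi_category,
            "seed": cfg.cohort.seed,
        },
        "limits": {
            "demographic": {k: list(v)
                            for k, v in cfg.limits.demographic.items()},
            "lab_removal": {k: list(v)
                            for k, v in cfg.limits.lab_removal.items()},
            "allow_negative": sorted(cfg.limits.allow_negative),
        },
        "contamination": cfg.contamination,
        "budget": cfg.budget,
        "selection_metric": cfg.selection_metric,
        "vote_threshold": cfg.vote_threshold,
        "split_ratio": cfg.split_ratio,
        "fitness": cfg.fitness,
        "priority": list(cfg.priority),
        "positive_sets": {k: sorted(v)
                          for k, v in cfg.positive_sets.items()},
        "ga": dataclasses.asdict(cfg.ga),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
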