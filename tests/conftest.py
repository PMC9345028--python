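"""Shared fixtures: a small strong-signal cohort reused across the suite."""

from __future__ import annotations

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from bgdecomp.pipeline import PipelineConfig, prepare_features
from bgdecomp.synthetic_cohort import CohortConfig, generate_cohort

settings.register_profile("suite", derandomize=True, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_config() -> CohortConfig:
    """~390 cases, strong pre-event signal."""
    return CohortConfig(n_patients=260, extra_admissions_mean=0.5, seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def prepared(small_cohort, small_config):
    cfg = PipelineConfig(cohort=small_config)
    feats, events, manifest, enc = prepare_features(small_cohort, cfg,
                                                    seed=0)
    return SimpleNamespace(config=cfg, features=feats, events=events,
                           manifest=manifest, encoding=enc)


def make_case_labs(rows, case_id="C1"):
    """Lab rows for a single case from (analyte, value, hours) tuples."""
    return pd.DataFrame({
        "case_id": case_id,
        "analyte": [r[0] for r in rows],
        "value": [float(r[1]) for r in rows],
        "hours": [float(r[2]) for r in rows],
    })


@pytest.fixture
def case_labs_factory():
    return make_case_labs


def ground_truth_hours(cohort) -> pd.DataFrame:
    gt = cohort.ground_truth.merge(
        cohort.admissions[["case_id", "admit_time"]], on="case_id")
    gt["event_hours"] = ((gt["event_time"] - gt["admit_time"])
                         / pd.Timedelta(hours=1))
    return gt
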