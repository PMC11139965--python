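"""Shared fixtures: synthetic cohorts are generated once per session."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from emgait.features import build_feature_table
from emgait.pipeline import cohort_to_limb_records
from emgait.synthetic import CohortSpec, generate_cohort

#: Cohort emulating the study's scale: 75 subjects, both limbs -> 150 rows.
DEFAULT_SPEC = CohortSpec(
    n_subjects=75,
    limbs_per_subject=2,
    trials_per_limb=5,
    cycles_per_trial=4,
    seed=42,
)

#: Null-effect cohort: severity decoupled from every EMG feature.
#: Single-limb subjects keep the rows independent for the calibration test.
NULL_SPEC = CohortSpec(
    n_subjects=400,
    limbs_per_subject=1,
    trials_per_limb=2,
    cycles_per_trial=3,
    severity_effect_cci=0.0,
    severity_effect_g=0.0,
    seed=13,
)

SMALL_SPEC = CohortSpec(
    n_subjects=4,
    limbs_per_subject=2,
    trials_per_limb=2,
    cycles_per_trial=3,
    seed=11,
)


def _table_for(spec: CohortSpec) -> pd.DataFrame:
    subjects = generate_cohort(spec)
    records, skipped = cohort_to_limb_records(subjects)
    assert not skipped, f"unexpected skipped limbs: {skipped}"
    return build_feature_table(records)


@pytest.fixture(scope="session")
def default_cohort_table() -> pd.DataFrame:
    return _table_for(DEFAULT_SPEC)


@pytest.fixture(scope="session")
def null_cohort_table() -> pd.DataFrame:
    return _table_for(NULL_SPEC)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_cohort_table(small_cohort) -> pd.DataFrame:
    records, _ = cohort_to_limb_records(small_cohort)
    return build_feature_table(records)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
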