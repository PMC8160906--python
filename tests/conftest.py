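"""Shared fixtures.

The two expensive session fixtures (a 120-subject null cohort feature table
and a full pipeline run on a 120-subject effectful cohort) are shared by the
acceptance tests; small throwaway cohorts are built locally where needed.
"""

from __future__ import annotations

import pandas as pd
import pytest

from somnoscreen.feature_catalog import compute_feature_table
from somnoscreen.pipeline import RunConfig, run_pipeline
from somnoscreen.synthetic_data import CohortSpec, generate_cohort

#: Scaled-down classifier settings used for cohort-level test runs; the
#: pipeline defaults stay at the method's standard constants.
FAST_CLASSIFY = dict(n_iterations=100, n_estimators=10, max_depth=3, top_models=12, combination_cap=2000)


@pytest.fixture(scope="session")
def null_cohort_features() -> pd.DataFrame:
    """Feature table of a 120-subject cohort with zero planted effects."""
    cohort = generate_cohort(CohortSpec(n_subjects=120, seed=100).null())
    return compute_feature_table(cohort.signals, cohort.anthro)


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-subject default-conditions cohort for unit-level checks."""
    return generate_cohort(CohortSpec(n_subjects=40, seed=1))


@pytest.fixture(scope="session")
def e2e_result():
    """Full pipeline run on the default 120-subject cohort (scaled-down
    classifier iteration counts; severity-linked arousal-index parameter)."""
    cohort = generate_cohort(CohortSpec(n_subjects=120, seed=11))
    cfg = RunConfig(seed=11, psg_params=("Total Arousal Index",), **FAST_CLASSIFY)
    return run_pipeline(cohort, cfg)
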