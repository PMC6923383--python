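"""Shared fixtures: small seeded cohorts built by the synthetic module."""

import numpy as np
import pytest

from traumapanel import (
    SyntheticSpec,
    generate_cohort,
    inject_missingness,
    study_spec,
)
from traumapanel.preprocess import preprocess_table, retain_complete_patients


@pytest.fixture(scope="session")
def study_cohort():
    """Study-shaped cohort (61 x 68/68/67) with missingness, plus truth."""
    spec = study_spec(seed=11)
    cohort, truth = generate_cohort(spec)
    cohort = inject_missingness(cohort, spec)
    return cohort, truth, spec


@pytest.fixture(scope="session")
def processed_tables(study_cohort):
    """Per-time-point tables after the canonical preprocessing pipeline."""
    cohort, truth, _ = study_cohort
    tables = retain_complete_patients(cohort.split_by_timepoint())
    out = []
    for t in tables:
        pt, _ = preprocess_table(t)
        out.append(pt)
    return out, truth


@pytest.fixture(scope="session")
def flat_cohort():
    """Single-time-point cohort, 3 planted markers among 20 noise
    features, no missingness — standardized, ready for selection."""
    from traumapanel.preprocess import autoscale

    spec = SyntheticSpec(
        n_patients=61,
        prevalence=0.35,
        timepoints=("t1",),
        n_features_per_timepoint=(23,),
        planted_markers=(("t1", 1.5),) * 3,
        clinical_scores=(),
        missing_rates={},
        seed=21,
    )
    cohort, truth = generate_cohort(spec)
    cohort, _ = autoscale(cohort)
    return cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
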