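"""Shared fixtures: small deterministic cohorts and hand-built trials."""

import numpy as np
import pytest

from surgstress.cohort import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size (58-trial) synthetic cohort, generated once per session."""
    return generate_cohort(CohortSpec(seed=20240502))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Six short trials for plumbing tests (I/O, CLI, table shapes)."""
    spec = CohortSpec(seed=99, n_trials=6, duration_s=30.0)
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)
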