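import numpy as np
import pytest

import cd4recon as c
from cd4recon.defaults import table_defaults


@pytest.fixture(scope="session")
def pop_truth():
    """Published typical values with diagonal random-effect variances."""
    return table_defaults()


@pytest.fixture(scope="session")
def small_cohort(pop_truth):
    """A small simulated cohort (n=24, ~3 years follow-up) reused across tests."""
    spec = c.CohortSpec(n_subjects=24, horizon_days=1095.0)
    skeletons = c.sample_demographics(spec, seed=42)
    schedules = c.sample_schedule(spec, len(skeletons), seed=42)
    dataset, truth = c.simulate_dataset(pop_truth, [], skeletons, schedules, seed=42)
    return dataset, truth
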