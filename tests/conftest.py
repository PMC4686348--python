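import numpy as np
import pytest

from neurosep import (
    StimulusParams,
    analyze_culture,
    generate_schedule,
    simulate_culture,
)

MASTER_SEED = 11


@pytest.fixture(scope="session")
def schedule():
    return generate_schedule(StimulusParams(), seed=MASTER_SEED)


@pytest.fixture(scope="session")
def culture(schedule):
    """One simulated reference-condition culture (counts + ground truth)."""
    return simulate_culture(schedule, seed=MASTER_SEED)


@pytest.fixture(scope="session")
def analyzed(schedule, culture):
    counts, _truth = culture
    return analyze_culture(counts, schedule, culture=1, seed=MASTER_SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(MASTER_SEED)
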