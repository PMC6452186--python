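import numpy as np
import pytest

from somascreen.filters import (
    build_recurrence_index,
    intersect_callsets,
    technical_filter,
)
from somascreen.simulate import SimulationConfig, generate_cohort

COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_cohort():
    """One default-configuration synthetic cohort, shared across tests."""
    return generate_cohort(SimulationConfig(seed=COHORT_SEED))


@pytest.fixture(scope="session")
def default_cohort_decisions(default_cohort):
    """Consensus candidates of the default cohort with filter decisions."""
    candidates = []
    for pair in default_cohort.pairs:
        merged, _ = intersect_callsets(pair.mutect_calls, pair.varscan_calls)
        candidates.extend(merged)
    index = build_recurrence_index(candidates)
    return [(c, technical_filter(c, index)) for c in candidates]


@pytest.fixture()
def rng():
    return np.random.default_rng(20181212)
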