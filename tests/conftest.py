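import numpy as np
import pytest
from hypothesis import settings

from cd138sno.simulate import SimulationConfig, generate_cohort

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: Small gene panel that still contains every marker gene; keeps cohort
#: generation fast in tests that do not study the expression component.
SMALL_GENES = {"protein_coding": 16, "snoRNA": 11, "lncRNA": 3, "misc_RNA": 2}


@pytest.fixture(scope="session")
def default_cohort():
    """One full default-size synthetic cohort, shared across tests."""
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture()
def small_config():
    return SimulationConfig(n_genes_per_biotype=dict(SMALL_GENES), seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
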