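import numpy as np
import pytest

from ldmf.resources import (
    load_printed_peptides,
    load_property_tables,
    load_reference_positive_set,
)
from ldmf.simulator import SimulationConfig, simulate


@pytest.fixture(scope="session")
def peptides():
    """The 20 assay peptides, keyed by id."""
    return {p.id: p for p in load_printed_peptides()}


@pytest.fixture(scope="session")
def tables():
    return load_property_tables()


@pytest.fixture(scope="session")
def reference_positive_set():
    """Synthetic stand-in positive set: (proteins, 18 motif sites)."""
    return load_reference_positive_set()


@pytest.fixture(scope="session")
def sim17():
    """The default synthetic world used by recovery tests."""
    return simulate(SimulationConfig(seed=17))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
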