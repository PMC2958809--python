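import numpy as np
import pytest

from mirscape.seedmatch import MirnaRecord
from mirscape.synthetic import SimConfig, SimBundle, simulate_all


@pytest.fixture(scope="session")
def mirna() -> MirnaRecord:
    return MirnaRecord(name="syn-miR-1", sequence="UCAGUACGAUAGCAUGGACGUU")


@pytest.fixture(scope="session")
def small_bundle() -> SimBundle:
    """A quick 600-gene study shared by unit tests."""
    return simulate_all(SimConfig(n_genes=600, seed=11))


@pytest.fixture(scope="session")
def study10k() -> SimBundle:
    """One full-scale (10,000-gene) study at the default conditions,
    shared by the calibration/recovery tests that only re-randomize the
    sequencing or expression layer on top of a fixed UTR corpus."""
    return simulate_all(SimConfig(n_genes=10_000, seed=0))


@pytest.fixture(scope="session")
def rng_factory():
    def make(seed: int) -> np.random.Generator:
        return np.random.default_rng(seed)

    return make
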