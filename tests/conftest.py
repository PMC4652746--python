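import numpy as np
import pytest

from coralign.index import build_index
from coralign.io import Genome
from coralign.simulate import make_genome

BASES = np.array(list("ACGT"))


def random_seq(rng, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """20 kb, 2 chromosomes, no engineered repeats; shared read-only."""
    return make_genome(20_000, 2, 0.0, seed=101)


@pytest.fixture(scope="session")
def small_index(small_genome):
    return build_index(small_genome)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
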