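import numpy as np
import pytest

from linc_chromatin.genome import GenomeSpec, partition_genome


@pytest.fixture(scope="session")
def default_spec() -> GenomeSpec:
    return GenomeSpec()


@pytest.fixture(scope="session")
def small_sequence(default_spec):
    """A 500-bead, 4-chromosome sequence used by the simulation tests."""
    return partition_genome(default_spec, 500)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
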