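import numpy as np
import pytest

from pausefold.simulate import SimulationConfig, simulate


@pytest.fixture(scope="session")
def sim_small():
    """A compact simulated data set shared by the faster integration tests."""
    return simulate(SimulationConfig(seed=11, n_genes=20, chrom_length=300_000))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
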