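import numpy as np
import pytest

from paradiverge.io_formats import ParalogPair
from paradiverge.simulate import SimulationConfig, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_pair():
    """The worked three-codon example pair."""
    return ParalogPair("toy1", "g1", "g2", "TTTAAAGGG", "TTTAAAGGA")


@pytest.fixture(scope="session")
def small_dataset():
    """A small but complete synthetic dataset shared across tests."""
    cfg = SimulationConfig(
        n_pairs=60,
        codons_per_gene=60,
        omega=0.5,
        coupling_lambda=1.0,
        de_fraction=0.3,
        enhancing_fraction=0.1,
        decreasing_fraction=0.1,
        seed=2024,
    )
    return simulate_dataset(cfg)
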