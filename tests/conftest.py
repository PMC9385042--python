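import numpy as np
import pytest

from odorinverse import neuralnet as nn
from odorinverse import synthetic as syn
from odorinverse.spectra import MassSpectrum, SpectrumLibrary


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_library():
    """Five short hand-made spectra on a 6-bin grid starting at m/z 51."""
    rows = [
        [1.0, 0.0, 0.4, 0.0, 0.0, 0.2],
        [0.0, 1.0, 0.0, 0.3, 0.0, 0.0],
        [0.2, 0.0, 1.0, 0.0, 0.5, 0.0],
        [0.0, 0.6, 0.0, 1.0, 0.0, 0.1],
        [0.0, 0.0, 0.3, 0.0, 1.0, 0.0],
    ]
    return SpectrumLibrary(
        [MassSpectrum(f"m{i}", 51, np.array(r)) for i, r in enumerate(rows)]
    )


@pytest.fixture
def small_world():
    """A 30-molecule synthetic world on the full 212-bin grid (noiseless)."""
    return syn.generate_world(n_molecules=30, noise_sd=0.0, seed=7)


@pytest.fixture
def small_model(small_world):
    """An untrained but structurally complete model matching the world's grid."""
    return small_world.planted_model


def make_random_net(sizes, seed=0, gain=1.0):
    return nn.xavier_init(sizes, np.random.default_rng(seed), gain=gain)
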