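import numpy as np
import pytest

from pccolumn import (
    DynamicsParams,
    LearningConfig,
    NetworkConfig,
    assemble_network,
    default_motif_spec,
    synth_dataset,
)
from pccolumn.plasticity import train

SEED = 1234


@pytest.fixture(scope="session")
def params():
    return DynamicsParams()


@pytest.fixture(scope="session")
def motif():
    return default_motif_spec()


@pytest.fixture(scope="session")
def toy_config(motif):
    return NetworkConfig(n_pix=64, n_rep=16, motif=motif)


@pytest.fixture(scope="session")
def toy_dataset():
    """16 training + 4 held-out low-rank 8x8 images."""
    return synth_dataset(20, 8, "lowrank", SEED)


@pytest.fixture(scope="session")
def trained_toy(toy_config, toy_dataset):
    """A toy network trained for 30 passes; shared across protocol tests."""
    net = assemble_network(toy_config, SEED)
    cfg = LearningConfig(batch_size=16, n_repeats=30)
    net, history = train(net, toy_dataset[:16], cfg, SEED)
    return net, history


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)
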