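import random

import pytest

from byssomap.simulate import SimulationConfig, write_dataset


@pytest.fixture(scope="session")
def synthetic_dataset(tmp_path_factory):
    """One default synthetic dataset shared across tests (seed 1)."""
    outdir = tmp_path_factory.mktemp("synthetic")
    truth = write_dataset(outdir, SimulationConfig(), seed=1)
    return outdir, truth


@pytest.fixture
def rng():
    return random.Random(12345)
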