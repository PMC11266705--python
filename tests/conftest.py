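import numpy as np
import pytest
from hypothesis import settings

from cpdseq import Genome, SimParams, simulate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_exp():
    """One moderate-depth synthetic experiment shared across tests."""
    return simulate_experiment(SimParams(seed=11, depth_0=150_000, depth_t=150_000))


@pytest.fixture()
def toy_genome():
    return Genome({"chr1": "AAAATTAAAA", "chr2": "ACGTACGTACGTACGT"})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
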