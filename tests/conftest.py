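import numpy as np
import pytest

from cernet import BHScenario, build_parameters, generate_network, make_motif
from cernet.synthetic_data import sample_transcription_rates


@pytest.fixture
def single_pair():
    return make_motif("single_pair")


@pytest.fixture
def v_motif():
    return make_motif("v_motif")


@pytest.fixture
def chain():
    return make_motif("chain")


@pytest.fixture
def small_network():
    """A 25x8 heavy-tailed bipartite network with default mode composition."""
    return generate_network(25, 8, 60, seed=3)


def random_parameters(network, beta_mean, cv, bh_level, seed):
    """Lognormal transcription-rate draw + BH assignment for a network."""
    rng = np.random.default_rng(seed)
    b = sample_transcription_rates(network.n_rna, 8.0, cv, rng.spawn(1)[0])
    beta = sample_transcription_rates(network.n_mirna, beta_mean, cv, rng.spawn(1)[0])
    return build_parameters(network, BHScenario.from_level(bh_level), b, beta)
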