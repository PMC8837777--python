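import numpy as np
import pytest

from engramsim import NeuronParams, build_network, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def neuron_params():
    return NeuronParams()


@pytest.fixture(scope="session")
def micro_sim():
    """A built micro two-region simulator (6 exc / 2 inh per region)."""
    spec, sched, kind = make_fixture("micro", seed=7)
    return build_network(spec), sched, kind
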