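import numpy as np
import pytest

from repeatspring.elasticity import ElasticNetwork, MechanicalTable


@pytest.fixture(scope="session")
def network():
    return ElasticNetwork.from_config({})


@pytest.fixture(scope="session")
def mech_table(network):
    return MechanicalTable(network)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
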