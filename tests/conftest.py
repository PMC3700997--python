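import copy

import pytest

from spinesync.biochemical import build_network, equilibrate
from spinesync.config import load_kinetics_config


@pytest.fixture(scope="session")
def kinetics_config():
    return load_kinetics_config()


@pytest.fixture(scope="session")
def _equilibrated_base(kinetics_config):
    return equilibrate(build_network(kinetics_config))


@pytest.fixture
def equilibrated_network(_equilibrated_base):
    """A fresh copy of the equilibrated plasticity network per test."""
    return copy.deepcopy(_equilibrated_base)
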