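import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

from mhc2lig.alphabet import RESIDUES
from mhc2lig.encoding import EncoderConfig, PeptideInstance
from mhc2lig.network import NetworkConfig, NetworkModel


def random_peptide(rng, length):
    return "".join(rng.choice(list(RESIDUES), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def encoder():
    return EncoderConfig()


@pytest.fixture
def encoder_ctx():
    return EncoderConfig(context_mode=True)


@pytest.fixture
def small_net(encoder):
    return NetworkModel(NetworkConfig(hidden_units=4, seed=7, iterations=10), encoder)


@pytest.fixture
def small_net_ctx(encoder_ctx):
    return NetworkModel(NetworkConfig(hidden_units=4, seed=7, iterations=10), encoder_ctx)


@pytest.fixture
def el_instance():
    return PeptideInstance("AAKFAAAAAAAAA", target=1.0, data_type="EL",
                           context_up="LPG", context_down="GSP")
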