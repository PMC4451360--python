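import numpy as np
import pytest

from instmfa.network import build_flux_mode_basis, build_reference_network
from instmfa.synthetic_data import make_dataset, make_truth


@pytest.fixture(scope="session")
def network():
    return build_reference_network()


@pytest.fixture(scope="session")
def basis(network):
    return build_flux_mode_basis(network)


@pytest.fixture(scope="session")
def table1_truth():
    return make_truth(seed=1, preset="table1_like")


@pytest.fixture(scope="session")
def noisefree_data(table1_truth, basis):
    """Dataset generated from the headline truth without observation noise."""
    return make_dataset(table1_truth, noise_cv=0.0, basis=basis)


@pytest.fixture(scope="session")
def noisy_data(table1_truth, basis):
    """Dataset with 5% multiplicative Gaussian noise on the time courses."""
    return make_dataset(table1_truth, noise_cv=0.05, seed=11, basis=basis)
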