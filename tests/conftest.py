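import numpy as np
import pytest

from capstress import (
    CapsuleParams,
    CcdSpec,
    additional_points,
    generate_ccd,
    simulate_dataset,
    verification_points,
)


@pytest.fixture(scope="session")
def default_params():
    return CapsuleParams()


@pytest.fixture(scope="session")
def basic_design():
    return generate_ccd(CcdSpec())


@pytest.fixture(scope="session")
def training_design(basic_design):
    """The 16 runs (basic + additional) that feed both models."""
    return basic_design.concat(additional_points())


@pytest.fixture(scope="session")
def full_design(training_design):
    return training_design.concat(verification_points())


@pytest.fixture(scope="session")
def simulated_full(full_design, default_params):
    """One noisy simulated dataset of the 20-run standard matrix (seed 0)."""
    return simulate_dataset(full_design, default_params)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
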