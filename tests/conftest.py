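import numpy as np
import pytest

from cpnet import CausalProteinNetwork


@pytest.fixture(scope="session")
def default_run():
    """Default-scale synthetic experiment (n=5000, 300 proteins, 50
    regulators, 3 confounders) fitted once and shared across tests."""
    model = CausalProteinNetwork.from_simulation(seed=7)
    return model, model.fit()


@pytest.fixture(scope="session")
def small_run():
    """Small, fast end-to-end run for module-level integration checks."""
    model = CausalProteinNetwork.from_simulation(
        seed=3, n_samples=1500, n_proteins=100, n_regulators=25
    )
    return model, model.fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
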