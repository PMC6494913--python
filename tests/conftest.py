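import matplotlib

matplotlib.use("Agg")

import numpy as np
import pytest

import premix as px
from premix.peaks import gamma2_from_table


@pytest.fixture(scope="session")
def toy():
    """Default toy complex with a planted 5-member true ensemble."""
    return px.make_toy_system(seed=11)


@pytest.fixture(scope="session")
def small_pool(toy):
    """Truth plus 300 decoys and the back-calculated Γ₂ matrix."""
    pool, truth_idx, matrix = px.make_pool_with_truth(toy, 300, seed=7)
    return pool, truth_idx, matrix


@pytest.fixture(scope="session")
def noiseless_gsets(toy):
    noise = px.NoiseModel(snr_para=float("inf"), snr_dia=float("inf"))
    tables = px.simulate_observed(toy, noise=noise, seed=0)
    return [gamma2_from_table(records, site) for site, records in tables.items()]


@pytest.fixture(scope="session")
def noisy_gsets(toy):
    tables = px.simulate_observed(toy, noise=px.NoiseModel(), seed=0)
    return [gamma2_from_table(records, site) for site, records in tables.items()]


@pytest.fixture(scope="session")
def dock_toy():
    return px.synthetic.make_dock_toy(seed=0)
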