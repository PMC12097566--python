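import numpy as np
import pytest

import nodcycles as nc
from nodcycles.synthetic import SimConfig, simulate_cycle_table


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated corpus shared across tests (300 nods, seed 7)."""
    cfg = SimConfig(n_nods=300, seed=7)
    table, truth = simulate_cycle_table(cfg)
    return cfg, table, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A quick Model5 fit on the small corpus (2 chains, 200 retained each)."""
    _, table, _ = small_sim
    spec = nc.model_catalog()[4]
    config = nc.MCMCConfig(chains=2, warmup=200, iterations=400, thin=1, seed=11)
    return nc.fit_mcmc(spec, table, config)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
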