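import numpy as np
import pytest

import ethomix as em


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated campaign with individual random effects (K=4)."""
    design = em.SimDesign(n_individuals=8, n_households=4, n_periods=3,
                          days_per_period=7, households_per_day=2,
                          day_start=8.0, day_end=9.5, K=4)
    formula = em.Formula(continuous={"age": 1},
                         categorical={"day_of_week": ["Saturday", "Sunday"]})
    return em.simulate_dataset(design, seed=20, formula=formula,
                               factors=("individual",))


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A quick 2-chain fit on the small campaign, reused across tests."""
    config = em.SamplerConfig(chains=2, iterations=300, warmup=150, seed=4,
                              target_accept=0.85)
    return em.fit(small_sim.model_data, config=config)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
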