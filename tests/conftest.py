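import numpy as np
import pandas as pd
import pytest

from ptsdsim.exposure import ExposureConfig, assign_tiers
from ptsdsim.synthpop import MarginalTable, default_marginals, generate_population


@pytest.fixture(scope="session")
def acs_marginals():
    return default_marginals("acs")


@pytest.fixture
def tiny_marginals():
    """Two-attribute marginal table with known proportions."""
    df = pd.DataFrame(
        {
            "attribute": ["sex", "sex", "age_band", "age_band"],
            "category": ["female", "male", "under_20", "20_44"],
            "proportion": [0.6, 0.4, 0.3, 0.7],
        }
    )
    return MarginalTable(df)


@pytest.fixture(scope="session")
def small_population(acs_marginals):
    """20k-agent population, session-scoped for speed; copy before mutating."""
    return generate_population(acs_marginals, 20_000, seed=7)


@pytest.fixture
def tiered_population(small_population):
    pop = small_population.copy()
    cfg = ExposureConfig(n_primary_students=90, n_primary_adults=10,
                         n_secondary_target=400)
    network = assign_tiers(pop, cfg, seed=11)
    return pop, cfg, network
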