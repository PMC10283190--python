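import numpy as np
import pandas as pd
import pytest

from vaxcount.data import HierarchicalCountData
from vaxcount.mcmc import SamplerConfig, run_mcmc
from vaxcount.model import ModelSpec
from vaxcount.simulate import scaled_presets, simulate_dataset

# parameter grid shared by the pmf/moment property tests
MU_GRID = (0.5, 2.0, 5.0, 9.0)
K_GRID = (0.5, 1.0, 5.0)
PI_GRID = (0.0, 0.2, 0.5)


@pytest.fixture(scope="session")
def tiny_data() -> HierarchicalCountData:
    design, truth = scaled_presets("tiny")
    return simulate_dataset(design, truth, seed=42)


@pytest.fixture(scope="session")
def desk_data() -> HierarchicalCountData:
    design, truth = scaled_presets("desk")
    return simulate_dataset(design, truth, seed=7)


@pytest.fixture(scope="session")
def flat_poisson_data() -> HierarchicalCountData:
    """40 i.i.d. Poisson(4) counts in a single community/state."""
    rng = np.random.default_rng(0)
    df = pd.DataFrame({
        "y": rng.poisson(4.0, size=40),
        "community_id": 0, "state_id": 0, "year": 2003, "weight": 1.0,
    })
    return HierarchicalCountData(df)


@pytest.fixture(scope="session")
def flat_poisson_fit(flat_poisson_data):
    """Intercept-only fixed-effects Poisson fit with 1000 retained draws."""
    spec = ModelSpec(family="poisson", random_effects=False)
    cfg = SamplerConfig(iterations=3000, warmup=1000, thin=2, chains=1, seed=5)
    return run_mcmc(flat_poisson_data, spec, config=cfg), flat_poisson_data, spec


@pytest.fixture(scope="session")
def tiny_poisson_fit(tiny_data):
    """Short multilevel Poisson fit on the tiny preset (2 chains)."""
    spec = ModelSpec(family="poisson", count_formula=tuple(tiny_data.covariate_names))
    cfg = SamplerConfig(iterations=1200, warmup=600, thin=3, chains=2, seed=9)
    return run_mcmc(tiny_data, spec, config=cfg), tiny_data, spec
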