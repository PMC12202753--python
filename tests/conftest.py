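import numpy as np
import pytest

from pomskat.simdata import SimulationConfig, maf_grid, simulate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """One modest J=3 replicate with covariate effects (null SNP effects)."""
    cfg = SimulationConfig(n=600, M=12, J=3, rho=0.5,
                           maf=tuple(maf_grid(12)), seed=101)
    G, X, y, latent = simulate_dataset(cfg, 0)
    return cfg, G, X, y, latent


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
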