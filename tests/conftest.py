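import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from commvar import McmcConfig, SimulationScenario, simulate_community


@pytest.fixture(scope="session")
def small_community():
    """A small noisy community reused by several fitting tests."""
    scenario = SimulationScenario(S=2, T=20, seed=11)
    latents, counts = simulate_community(scenario)
    return scenario, latents, counts


@pytest.fixture()
def short_config():
    """A deliberately short MCMC schedule for structural (non-inferential) tests."""
    return McmcConfig(chains=2, iterations=400, burn_in=200, thin=2, seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
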