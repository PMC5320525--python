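import numpy as np
import pytest

import superdna as sd


@pytest.fixture(scope="session")
def small_genome():
    """A 600 kb simulated bacterial genome shared across unit tests."""
    cfg = sd.SimulationConfig(genome_size=600_000, seed=101)
    return cfg, sd.simulate_bacterial(cfg)


@pytest.fixture(scope="session")
def desk_genome():
    """The 5 Mb default-parameter genome used by the closed-loop checks."""
    cfg = sd.SimulationConfig(genome_size=5_000_000, seed=202)
    return cfg, sd.simulate_bacterial(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
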