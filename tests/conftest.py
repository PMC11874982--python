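import numpy as np
import pytest

from defenseflux.simulate import SimulationConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small simulated species shared across tests (cheap, deterministic)."""
    cfg = SimulationConfig(
        n_genomes=60,
        n_mge_families=12,
        n_families={"prophage": 8, "plasmid": 8, "transposon": 8, "neutral": 30},
        seed=42,
    )
    return generate_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
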