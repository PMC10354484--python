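import numpy as np
import pytest

from whalepreg.datasets import load_pcfg_females
from whalepreg.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def pcfg():
    """Bundled study dataset of female whale-years."""
    return load_pcfg_females()


@pytest.fixture(scope="session")
def sim_small():
    """A small synthetic dataset exercising every QC path."""
    return simulate_dataset(SimulationConfig(), rng=np.random.default_rng(20160615))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
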