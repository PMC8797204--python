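import pytest

from lncse.simulate import SimConfig, simulate_dataset
from lncse import se as se_mod


@pytest.fixture(scope="session")
def default_data():
    """One full-size synthetic dataset (seed 1) shared across tests."""
    return simulate_dataset(SimConfig(seed=1))


@pytest.fixture(scope="session")
def called_se(default_data):
    d = default_data
    return se_mod.call_super_enhancers(d.peaks, d.h3k27ac, d.annotation, d.blacklist)


@pytest.fixture(scope="session")
def compact_data():
    """A reduced 5 Mb dataset for cheaper end-to-end checks."""
    return simulate_dataset(SimConfig.compact(seed=7))
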