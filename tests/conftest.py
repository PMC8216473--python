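import pytest
from hypothesis import settings

from agoclip.synthetic import SyntheticConfig, simulate_dataset

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_config() -> SyntheticConfig:
    return SyntheticConfig(
        seed=11,
        n_true_peaks=60,
        n_decoy_peaks=10,
        n_mirnas=6,
        n_background_genes=100,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate_dataset(small_config)
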