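import pytest
from hypothesis import settings

from zwscan import simdata

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")

# a deliberately small cohort so the whole simulated study fits in seconds
SMALL = dict(n_autosomal_genes=150, n_z_genes=90, mean_depth=300)


@pytest.fixture(scope="session")
def small_config() -> simdata.SimConfig:
    return simdata.SimConfig(**SMALL, seed=42)


@pytest.fixture(scope="session")
def small_bundle(small_config) -> simdata.SimBundle:
    return simdata.simulate_dataset(small_config)
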