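import pytest
from hypothesis import HealthCheck, settings

from splicemaps import synthetic

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def dataset():
    """One full synthetic dataset at the default study conditions."""
    return synthetic.generate_dataset(synthetic.GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    return synthetic.GeneratorConfig(
        seed=3, n_genes=12, n_decoy_genes=3, n_chroms=2, n_trios=8,
        n_candidate_dnvs=6,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return synthetic.generate_dataset(small_config)
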