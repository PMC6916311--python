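import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_config():
    """Reduced sampler profile for unit tests."""
    from biasmeta import MCMCConfig

    return MCMCConfig(n_chains=3, n_iter=4000, n_burnin=1000, seed=123)
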