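import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """One small synthetic dataset shared across tests (seed 11, n=5/group)."""
    from cernet.simulate import SimulationConfig, generate_dataset

    return generate_dataset(SimulationConfig(seed=11, n_replicates=5))
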