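import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_dataset():
    """20 clearly separable synthetic samples, shared across tests."""
    from dcai.synthetic import SynthConfig, gen_dataset
    dataset, _ = gen_dataset(SynthConfig(n_samples=20, delta=1.0, seed=1))
    return dataset
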