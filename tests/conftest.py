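import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_system():
    """A small simulated regulatory system for sampler-level tests."""
    from tfnet.simulate import benchmark_scenario

    return benchmark_scenario(
        np.random.default_rng(7), G=24, N=12, K=2, L=3, sparsity=0.2
    )
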