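import numpy as np
import pytest

from svload import SimParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """Small, fast parameter set for smoke-level engine tests."""
    return SimParams(K=30, generations=50, outcrossing=0.5, seed=7, record_every=5)


@pytest.fixture
def fig6_params():
    """The study's headline parameter set (carrying capacity 1000)."""
    return SimParams(
        L=10_000, mu=0.01, nu=0.001, r=1e-4, a=0.001, b=0.0006,
        k=1.0, theta=2.0, K=1000, outcrossing=1.0, fitness_mode="count",
    )
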