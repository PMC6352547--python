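import numpy as np
import pytest

from hexacpg import ModelParams


@pytest.fixture(scope="session")
def default_params() -> ModelParams:
    """Default model: surrogate connectivity, sin coupling, sigma=0.01, k=0."""
    return ModelParams()


@pytest.fixture(scope="session")
def feedback_params(default_params) -> ModelParams:
    """The feedback regime used throughout the bout experiments (k = Gamma = 1)."""
    return default_params.with_(k=1.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def random_connectivity_params(rng):
    """A random row-normalized parameter set satisfying the sign constraints."""
    from hexacpg import ConnectivityParams

    l1 = rng.uniform(0.2, 0.8)
    b1 = rng.uniform(0.1, 0.5)
    f2 = rng.uniform(0.1, 0.8 - b1)
    l3 = rng.uniform(-1.0, -0.1)
    return ConnectivityParams(
        l1=l1, f1=1.0 - l1,
        b1=b1, f2=f2, l2=1.0 - b1 - f2,
        l3=l3, b2=1.0 - l3,
    )
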