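import numpy as np
import pytest

from radibias.phantom import PhantomSpec


@pytest.fixture(scope="session")
def small_spec() -> PhantomSpec:
    """Scaled-down phantom for fast tests: same design, smaller problem size."""
    return PhantomSpec(
        grid_shape=(48, 48, 32), insert_scale=0.55, n_replicates=3, seed=123
    )


@pytest.fixture(scope="session")
def tiny_spec() -> PhantomSpec:
    """Smallest usable phantom (smoke tests)."""
    return PhantomSpec(
        grid_shape=(40, 40, 28), insert_scale=0.5, n_replicates=2, seed=5
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
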