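import numpy as np
import pytest

from pennadti import PhantomSpec, fit_tensor, generate_phantom

SMALL_SHAPE = (32, 48, 5)


@pytest.fixture(scope="session")
def small_phantom():
    """Noiseless bipennate phantom on a reduced grid (stack, table, truth)."""
    return generate_phantom(PhantomSpec(shape=SMALL_SHAPE))


@pytest.fixture(scope="session")
def small_field(small_phantom):
    stack, table, truth = small_phantom
    return fit_tensor(stack, table, mask=truth.muscle_mask)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260924)
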