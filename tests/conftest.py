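import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240817)


def random_measurement(rng, n_min=0, n_max=120):
    """Random cell array exercising all scoring branches (incl. zero controls)."""
    n = int(rng.integers(n_min, n_max + 1))
    test = rng.poisson(rng.uniform(0.5, 6.0), n)
    red = rng.poisson(2.0, n)
    green = rng.poisson(2.0, n)
    # occasionally knock out both controls in a few cells
    knock = rng.random(n) < 0.05
    red[knock] = 0
    green[knock] = 0
    return np.column_stack([test, red, green]).astype(np.int64)
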