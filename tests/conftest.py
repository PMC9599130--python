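import numpy as np
import pytest

from spillsim import GeometryParams, generate_geometry


@pytest.fixture(scope="session")
def default_geometry():
    """One calibrated default tissue realization shared across tests."""
    return generate_geometry(GeometryParams(), seed=101)


@pytest.fixture(scope="session")
def small_geometry():
    """A cheaper 2 μm arena for fast dynamics tests."""
    params = GeometryParams(arena_edge=2.0, n_test_points=50_000)
    return generate_geometry(params, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
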