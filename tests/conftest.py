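import numpy as np
import pytest

from ringfus import Medium, RingArraySpec, build_ring_geometry


@pytest.fixture(scope="session")
def medium():
    return Medium()


@pytest.fixture(scope="session")
def ring_geometry():
    """The default 512-element ring design, shared across tests."""
    return build_ring_geometry(RingArraySpec())


@pytest.fixture(scope="session")
def small_geometry():
    """A 64-element ring, cheap enough for solver tests."""
    return build_ring_geometry(RingArraySpec(n_elements=64, pitch=0.3))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
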