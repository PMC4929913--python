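import numpy as np
import pytest

from homerange import SimulationConfig, SiteField


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A light configuration for fast hand-traceable trials."""
    return SimulationConfig(n_sites=0, n_steps=10)


@pytest.fixture
def two_site_field():
    """Two sites straddling the start position: a canonical pin cycle."""
    return SiteField(np.array([[51.0, 50.0], [49.0, 50.0]]))


def make_field(*points) -> SiteField:
    return SiteField(np.array(points, dtype=float))
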