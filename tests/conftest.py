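import numpy as np
import pytest

from rfbm.domains import CrowdedDiskDomain, PolarRingDomain, RectangleDomain


@pytest.fixture(scope="session")
def ring():
    """Lobed ring with the reference geometry (outer 100(1+0.5cos^2 4phi), inner 50)."""
    return PolarRingDomain()


@pytest.fixture(scope="session")
def plain_disk():
    return CrowdedDiskDomain(radius=10.0, obstacles=())


@pytest.fixture()
def strip():
    """1D-like strip: x confined to [0, 10], y free."""
    return RectangleDomain(x_min=0.0, x_max=10.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
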