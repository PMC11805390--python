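import numpy as np
import pytest

import pvsq


@pytest.fixture(scope="session")
def small_phantom():
    """A default phantom reused by read-only tests."""
    spec = pvsq.PhantomSpec()
    return pvsq.generate_phantom(spec, seed=42)


@pytest.fixture(scope="session")
def tube_volume():
    """A clean dark tube along z in a bright background, 32^3."""
    shape = (32, 32, 32)
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    r = np.sqrt((yy - 15.5) ** 2 + (xx - 15.5) ** 2)
    data = np.where(r <= 1.2, 40.0, 110.0)
    from scipy.ndimage import gaussian_filter

    return pvsq.Volume3D(gaussian_filter(data, 0.5))


@pytest.fixture(scope="session")
def cohort_default():
    return pvsq.generate_cohort(seed=7)
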