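import numpy as np
import pytest

from respimoco.phantom import (Lesion, PhantomSpec, build_phantom,
                               default_spec, make_motion)


@pytest.fixture(scope="session")
def phantom():
    """Default 128 x 128 (3 mm) thorax slab with one 10-mm liver lesion."""
    return build_phantom(default_spec())


@pytest.fixture(scope="session")
def motion(phantom):
    """Default ground-truth motion: 20-mm excursion, 2 mm*s hysteresis."""
    return make_motion(phantom)


@pytest.fixture(scope="session")
def small_phantom():
    """64 x 64 slab for cheap reconstruction-level tests."""
    spec = PhantomSpec(grid_shape=(64, 64), spacing_mm=(3.0, 3.0),
                       lesions=[Lesion((105.0, 126.0), 12.0, 12.0)])
    return build_phantom(spec)


@pytest.fixture(scope="session")
def small_motion(small_phantom):
    return make_motion(small_phantom)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
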