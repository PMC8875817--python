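import numpy as np
import pytest
from hypothesis import settings

from gaitfit.depth_io import DEFAULT_INTRINSICS
from gaitfit.geometry import FootShape, ShankShape
from gaitfit.synthetic import default_shapes

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

#: render/track resolution used throughout the suite (half the default
#: intrinsics fixture): keeps sequence tests fast without changing geometry
TEST_INTRINSICS = DEFAULT_INTRINSICS.scaled(0.5)


@pytest.fixture(scope="session")
def intrinsics():
    return TEST_INTRINSICS


@pytest.fixture(scope="session")
def shapes():
    return default_shapes()


@pytest.fixture(scope="session")
def foot():
    return FootShape(r=35.0, l=250.0, h=70.0, d=12.0)


@pytest.fixture(scope="session")
def shank():
    return ShankShape(r1=35.0, r2=45.0, s=350.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_foot_shape(rng) -> FootShape:
    r = rng.uniform(25.0, 45.0)
    return FootShape(
        r=r,
        l=rng.uniform(r + 120.0, r + 240.0),
        h=rng.uniform(50.0, 100.0),
        d=rng.uniform(0.0, 0.4) * r,
    )


def random_shank_shape(rng) -> ShankShape:
    r1 = rng.uniform(25.0, 50.0)
    return ShankShape(r1=r1, r2=r1 + rng.uniform(0.0, 20.0), s=rng.uniform(250.0, 420.0))
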