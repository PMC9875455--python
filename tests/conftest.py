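import numpy as np
import pytest

from cardiodti import DiffusionProtocol, PhantomSpec, build_phantom


@pytest.fixture(scope="session")
def default_protocol():
    return DiffusionProtocol.default()


@pytest.fixture(scope="session")
def small_spec():
    """A small single-slice phantom for fast tests."""
    return PhantomSpec(
        grid_shape=(32, 32, 1),
        inner_radius=6.0,
        outer_radius=14.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def default_phantom():
    spec = PhantomSpec()
    return spec, build_phantom(spec)


def random_rotations(n, rng):
    """Uniform random rotation matrices via normalized quaternions."""
    q = rng.normal(size=(n, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack(
        [
            1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w),
            2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w),
            2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y),
        ],
        axis=1,
    ).reshape(n, 3, 3)
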