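import numpy as np
import pytest

from naear import PhantomSpec, SequenceParams, build_phantom, make_trajectory
from naear.phantom import B0Params


@pytest.fixture(scope="session")
def default_phantom():
    """Full-size default phantom (96^3 at 1 mm)."""
    return build_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def small_params():
    """Scaled-down acquisition: 64 mm FOV at 2 mm -> 32^3 grid."""
    return SequenceParams(fov=64.0, resolution=2.0)


@pytest.fixture(scope="session")
def small_cartesian(small_params):
    return make_trajectory(small_params, "cartesian")


@pytest.fixture(scope="session")
def small_cones(small_params):
    return make_trajectory(small_params, "cones", n_readouts=700, samples_per_readout=36)


@pytest.fixture(scope="session")
def uniform_phantom_60hz():
    """Both-ear phantom with spatially uniform +60 Hz off-resonance."""
    spec = PhantomSpec(
        grid_shape=(48, 48, 48),
        voxel_size=2.0,
        b0_params=B0Params(
            amplitude_hz=0.0, boundary_amplitude_hz=0.0, constant_hz=60.0
        ),
    )
    return build_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
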