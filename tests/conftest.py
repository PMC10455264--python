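import numpy as np
import pytest

from splenovol.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def ellipsoid_spec():
    """Undeformed ellipsoid at the acceptance resolution (1x1 mm in-plane,
    3 mm slices), semi-axes >= 30 mm."""
    return PhantomSpec(
        semi_axes=(60.0, 40.0, 30.0),
        deform_amplitude=0.0,
        in_plane_spacing=(1.0, 1.0),
        slice_spacing=3.0,
        grid_shape=(40, 300, 300),
        body_radius=110.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def ellipsoid_phantom(ellipsoid_spec):
    return generate_phantom(ellipsoid_spec)


@pytest.fixture(scope="session")
def coarse_spec():
    """Small deformed phantom on a coarse grid for fast pipeline tests."""
    return PhantomSpec(
        semi_axes=(50.0, 40.0, 35.0),
        deform_amplitude=0.15,
        in_plane_spacing=(2.0, 2.0),
        slice_spacing=3.0,
        grid_shape=(40, 140, 140),
        body_radius=95.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def coarse_phantom(coarse_spec):
    return generate_phantom(coarse_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
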