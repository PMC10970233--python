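import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from qfish3d import (  # noqa: E402
    DetectionParams,
    ImageStack3D,
    SimulationConfig,
    VoxelGeometry,
    simulate_nucleus_stack,
)


@pytest.fixture(scope="session")
def geometry():
    return VoxelGeometry()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def render_single_spot(
    shape=(15, 48, 48),
    center=(7.0, 24.0, 24.0),
    amplitude=50.0,
    sigma_xy_nm=56.0,
    sigma_z_nm=170.0,
    background=2.0,
    geometry=VoxelGeometry(),
    noise_seed=None,
):
    """One anisotropic Gaussian spot on constant background; Poisson
    noise only when a seed is given."""
    zz, yy, xx = np.mgrid[0 : shape[0], 0 : shape[1], 0 : shape[2]].astype(float)
    sz = sigma_z_nm / geometry.dz_nm
    sxy = sigma_xy_nm / geometry.dx_nm
    lam = background + amplitude * np.exp(
        -0.5 * (((zz - center[0]) / sz) ** 2 + ((yy - center[1]) / sxy) ** 2 + ((xx - center[2]) / sxy) ** 2)
    )
    if noise_seed is None:
        vox = np.rint(lam).astype(np.int64)
    else:
        vox = np.random.default_rng(noise_seed).poisson(lam).astype(np.int64)
    return ImageStack3D(vox, geometry)


@pytest.fixture(scope="session")
def small_nucleus():
    """A compact noiseless nucleus used by several detection tests."""
    cfg = SimulationConfig(
        n_spots=12,
        nucleus_semiaxes_nm=(1200.0, 1500.0, 1500.0),
        shape=(15, 128, 128),
        min_separation_nm=600.0,
        poisson_noise=False,
        seed=7,
    )
    return simulate_nucleus_stack(cfg), cfg


@pytest.fixture(scope="session")
def default_det_params():
    return DetectionParams()
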