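import numpy as np
import pytest

from ratparc import phantom as ph


@pytest.fixture(scope="session")
def small_spec() -> ph.PhantomSpec:
    """Fast phantom: 32x32x12 grid, 6 regions, 1-voxel sinusoidal warp."""
    return ph.PhantomSpec(
        shape=(32, 32, 12),
        n_rois=6,
        amplitude=1.0,
        wavelength=10.0,
        noise_sd=0.05,
        enhancement_rois=(1,),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_spec):
    return ph.make_phantom(small_spec)


@pytest.fixture(scope="session")
def bundle8():
    """Full-size phantom with 8 well-resolved regions (default deformation)."""
    return ph.make_phantom(ph.PhantomSpec(seed=7, n_rois=8))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def random_affine_params(rng: np.random.Generator) -> np.ndarray:
    """Well-conditioned random 12-parameter vector (mm/rad/scale/shear)."""
    p = np.zeros(12)
    p[0:3] = rng.uniform(-2, 2, 3)
    p[3:6] = rng.uniform(-0.2, 0.2, 3)
    p[6:9] = rng.uniform(-0.1, 0.1, 3)
    p[9:12] = rng.uniform(-0.05, 0.05, 3)
    return p
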