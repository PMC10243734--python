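import numpy as np
import pytest

from projlddmm.grids_io import ImageVolume, SliceImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_volume(rng):
    """A smooth random 2-channel volume with anisotropic spacing."""
    from scipy.ndimage import gaussian_filter

    data = np.stack(
        [gaussian_filter(rng.standard_normal((9, 11, 13)), 1.0) for _ in range(2)],
        axis=-1,
    )
    return ImageVolume(data, spacing=(0.4, 0.3, 0.2), origin=(-1.0, 0.5, 2.0))


@pytest.fixture
def affine_volume():
    """Volume whose single channel is an affine function of world position."""
    shape = (6, 7, 8)
    spacing = np.array([0.5, 0.25, 0.4])
    origin = np.array([-1.0, 0.0, 1.0])
    ax = [origin[a] + spacing[a] * np.arange(shape[a]) for a in range(3)]
    Z, Y, X = np.meshgrid(*ax, indexing="ij")
    data = 2.0 * Z - 1.5 * Y + 0.7 * X + 0.3
    return ImageVolume(data, spacing, origin)


@pytest.fixture
def random_slice(rng):
    return SliceImage(
        rng.uniform(size=(16, 20, 3)), spacing=(0.1, 0.1), origin=(0.0, 0.0),
        z_position=1.5,
    )
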