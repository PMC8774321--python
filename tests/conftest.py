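import numpy as np
import pytest

from shapefeature.grid import BinaryMask, VoxelGrid
from shapefeature.phantom import simulate_cohort


def make_ball_mask(radius: float, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> BinaryMask:
    """Digitized ball of the given radius (mm), centred on the grid."""
    sp = np.asarray(spacing, dtype=float)
    half = np.ceil(radius / sp).astype(int) + margin
    axes = [np.arange(-h, h + 1) * s for h, s in zip(half, sp)]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    return BinaryMask(values=x**2 + y**2 + z**2 <= radius**2, spacing=tuple(sp))


def make_box_mask(extent, spacing=(1.0, 1.0, 1.0), margin: int = 2) -> BinaryMask:
    """Axis-aligned solid box of ``extent`` voxels per axis, padded by margin."""
    shape = tuple(e + 2 * margin for e in extent)
    values = np.zeros(shape, dtype=bool)
    sl = tuple(slice(margin, margin + e) for e in extent)
    values[sl] = True
    return BinaryMask(values=values, spacing=spacing)


@pytest.fixture(scope="session")
def ball_mask():
    return make_ball_mask


@pytest.fixture(scope="session")
def box_mask():
    return make_box_mask


@pytest.fixture(scope="session")
def default_cohort():
    """The default two-group phantom cohort (23 AD-like vs 27 non-AD-like)."""
    return simulate_cohort(n_pos=23, n_neg=27, seed=7, keep_volumes=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture()
def random_grid():
    def _make(seed=0, shape=(6, 5, 4), spacing=(2.0, 2.0, 3.75)):
        r = np.random.default_rng(seed)
        return VoxelGrid(values=r.random(shape), spacing=spacing)

    return _make
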