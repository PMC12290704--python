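import numpy as np
import pytest

from atrophynet import DisplacementField, Ellipsoid, ImageGrid, PhantomSpec, ScalarVolume


@pytest.fixture(scope="session")
def grid48():
    return ImageGrid((48, 48, 48))


@pytest.fixture(scope="session")
def small_spec():
    """A 24^3 phantom for fast training-path tests (same structure,
    smaller regions; grid divisible by the default U-Net pooling factor)."""
    return PhantomSpec(
        grid_shape=(24, 24, 24),
        tissue_region=Ellipsoid((15.5, 12.0, 12.0), (4.0, 4.0, 3.5)),
        fluid_region=Ellipsoid((5.5, 12.0, 12.0), (2.2, 2.2, 2.0)),
        rate_range=(0.01, 0.05),
        n_timepoints=(3, 3),
        interval_range=(0.5, 1.5),
        support_factor=1.35,
        center_jitter=0.5,
    )


def make_ball_mask(grid: ImageGrid, center, radius) -> np.ndarray:
    coords = grid.coordinates()
    return (np.linalg.norm(coords - np.asarray(center), axis=-1) <= radius).astype(
        float
    )


def uniform_scaling_field(grid: ImageGrid, scale: float, center) -> DisplacementField:
    """u(x) = (s - 1)(x - c): a global uniform contraction/expansion."""
    coords = grid.coordinates()
    return DisplacementField(grid, (scale - 1.0) * (coords - np.asarray(center)))


class GaussianBumpField:
    """Analytic smooth displacement field, evaluable at arbitrary points.

    A sum of Gaussian bumps with random centres, widths and directions;
    used to build oracles (e.g. refined-grid derivatives) that need the
    field off the voxel lattice.
    """

    def __init__(self, extent_mm, n_bumps=4, amplitude=1.0, seed=0):
        rng = np.random.default_rng(seed)
        extent = np.asarray(extent_mm, dtype=float)
        self.centers = rng.uniform(0.2, 0.8, size=(n_bumps, 3)) * extent
        self.sigmas = rng.uniform(5.0, 9.0, size=n_bumps)
        directions = rng.standard_normal((n_bumps, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        self.amps = directions * rng.uniform(0.3, 1.0, size=(n_bumps, 1)) * amplitude

    def __call__(self, coords: np.ndarray) -> np.ndarray:
        u = np.zeros_like(coords, dtype=float)
        for c, s, a in zip(self.centers, self.sigmas, self.amps):
            r2 = ((coords - c) ** 2).sum(axis=-1)
            u += np.exp(-r2 / (2 * s**2))[..., None] * a
        return u

    def on_grid(self, grid: ImageGrid) -> DisplacementField:
        return DisplacementField(grid, self(grid.coordinates()))


@pytest.fixture
def bump_field_factory():
    return GaussianBumpField


@pytest.fixture
def ball_mask_factory():
    return make_ball_mask


@pytest.fixture
def scaling_field_factory():
    return uniform_scaling_field


def random_volume(grid: ImageGrid, seed: int) -> ScalarVolume:
    rng = np.random.default_rng(seed)
    return ScalarVolume(grid, rng.standard_normal(grid.shape))
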