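"""Shared fixtures: small deterministic grids and one full-size phantom.

The default phantom is expensive (~6 s) and is reused session-wide by the
round-trip, error-injection, demons, and suite tests.
"""

import numpy as np
import pytest

import dirqa as dq
from dirqa.grid import ImageGrid, ScalarVolume, VectorField


@pytest.fixture(scope="session")
def small_grid() -> ImageGrid:
    return ImageGrid(shape=(8, 8, 8), spacing=(2.0, 1.5, 3.0), origin=(-4.0, 0.0, 10.0))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)


@pytest.fixture()
def random_volume(small_grid, rng) -> ScalarVolume:
    return ScalarVolume(small_grid, rng.normal(50.0, 30.0, size=small_grid.shape))


def smooth_random_field(grid: ImageGrid, rng, amplitude_mm: float = 1.5) -> VectorField:
    """Small smooth random displacement field (safely diffeomorphic)."""
    from scipy.ndimage import gaussian_filter

    disp = np.stack(
        [gaussian_filter(rng.standard_normal(grid.shape), 2.0) for _ in range(3)],
        axis=-1,
    )
    disp *= amplitude_mm / max(np.abs(disp).max(), 1e-12)
    return VectorField(grid, disp)


@pytest.fixture(scope="session")
def default_phantom() -> dq.Phantom:
    """Full 64^3 phantom under the default study conditions."""
    return dq.build_phantom(plan=dq.default_plan(), seed=0)
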