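import numpy as np
import pytest

from lungcad.phantoms import PhantomParams, make_benign_phantom, make_malignant_phantom


@pytest.fixture(scope="session")
def benign_record():
    return make_benign_phantom(PhantomParams(radius_mm=8.0, seed=1))


@pytest.fixture(scope="session")
def malignant_record():
    return make_malignant_phantom(seed=2)


@pytest.fixture(scope="session")
def ramp_volume():
    """f(x, y, z) = x + 2y + 3z on a 16^3 grid."""
    ax = np.arange(16, dtype=float)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x + 2 * y + 3 * z


def digital_ball(radius: int, n: int | None = None) -> np.ndarray:
    """Rasterised ball centred between voxels (even grid, 2r-voxel bounding box)."""
    n = n or int(2 * radius + 4)
    c = (n - 1) / 2.0
    ax = np.arange(n) - c
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return x * x + y * y + z * z <= radius * radius


def parametric_circle(radius: float = 30.0, n: int | None = None) -> np.ndarray:
    n = n or int(round(2 * np.pi * radius))
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([radius * np.sin(t), radius * np.cos(t)])


def parametric_star(radius: float = 100.0, lobes: int = 8, amp: float = 0.3,
                    n: int = 2400) -> np.ndarray:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = radius * (1 + amp * np.sin(lobes * t))
    return np.column_stack([r * np.sin(t), r * np.cos(t)])
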