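"""Shared fixtures: small phantoms and analytic mesh fixtures, generated at test time."""

import numpy as np
import pytest
import trimesh

import ribalign as ra
from ribalign.volume import Mask


@pytest.fixture(scope="session")
def small_spec() -> ra.PhantomSpec:
    """Down-scaled noiseless torso phantom for fast unit tests."""
    return ra.PhantomSpec(
        torso_half_axes=(110.0, 64.0, 180.0),
        n_rib_pairs=5,
        voxel_spacing=(4.0, 4.0, 4.0),
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_labels(small_spec) -> ra.Volume:
    return ra.generate_labels(small_spec)


@pytest.fixture(scope="session")
def small_volume(small_spec) -> ra.Volume:
    return ra.generate_torso_volume(small_spec)


@pytest.fixture(scope="session")
def sphere_mask() -> Mask:
    """Solid voxel ball of radius 20 mm at 1 mm spacing."""
    r, n = 20.0, 48
    g = np.arange(n) - (n - 1) / 2.0
    x, y, z = np.meshgrid(g, g, g, indexing="ij")
    return Mask(x**2 + y**2 + z**2 <= r**2, (1.0, 1.0, 1.0), (-(n - 1) / 2.0,) * 3)


@pytest.fixture(scope="session")
def sphere_mesh_r100() -> ra.SurfaceMesh:
    """Icosphere of radius 100 mm (skin fixture for surface distances)."""
    s = trimesh.creation.icosphere(subdivisions=4, radius=100.0)
    return ra.SurfaceMesh(np.asarray(s.vertices), np.asarray(s.faces), "skin")


@pytest.fixture(scope="session")
def generic_landmarks() -> np.ndarray:
    """Five well-spread noncollinear points (mm scale)."""
    return np.array(
        [
            [0.0, 90.0, 200.0],
            [-110.0, 50.0, 230.0],
            [110.0, 50.0, 230.0],
            [0.0, 95.0, 80.0],
            [0.0, -80.0, 260.0],
        ]
    )
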