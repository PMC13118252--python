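"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from vmatct.geometry import ConeBeamGeometry, forward_project_view


@pytest.fixture(scope="session")
def tiny_geometry():
    """8^3 volume / 12^2 detector: small enough for dense-matrix oracles."""
    return ConeBeamGeometry(volume_shape=(8, 8, 8), voxel_size_mm=4.0,
                            detector_rows=12, detector_cols=12,
                            detector_pixel_pitch_mm=6.0)


@pytest.fixture(scope="session")
def small_geometry():
    """16^3 volume / 20^2 detector for the adjoint-identity oracle."""
    return ConeBeamGeometry(volume_shape=(16, 16, 16), voxel_size_mm=4.0,
                            detector_rows=20, detector_cols=20,
                            detector_pixel_pitch_mm=5.0)


def dense_system_matrix(geometry: ConeBeamGeometry, angle_deg: float):
    """Materialize the forward operator column by column (basis volumes).

    Independent oracle: uses only the public single-view forward
    projection, applied to every voxel indicator.
    """
    nvox = int(np.prod(geometry.volume_shape))
    nray = geometry.detector_rows * geometry.detector_cols
    R = np.zeros((nray, nvox))
    basis = np.zeros(geometry.volume_shape)
    for n in range(nvox):
        idx = np.unravel_index(n, geometry.volume_shape)
        basis[idx] = 1.0
        R[:, n] = forward_project_view(basis, geometry, angle_deg).ravel()
        basis[idx] = 0.0
    return R


@pytest.fixture(scope="session")
def dense_R_tiny(tiny_geometry):
    return dense_system_matrix(tiny_geometry, 30.0)


@pytest.fixture(scope="session")
def dense_R_small(small_geometry):
    return dense_system_matrix(small_geometry, 42.0)


def ray_box_chord(source, direction, lo, hi):
    """Analytic chord length of a ray through an axis-aligned box."""
    source = np.asarray(source, float)
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    t0, t1 = -np.inf, np.inf
    for a in range(3):
        if abs(direction[a]) < 1e-12:
            if source[a] < lo[a] or source[a] > hi[a]:
                return 0.0
            continue
        ta = (lo[a] - source[a]) / direction[a]
        tb = (hi[a] - source[a]) / direction[a]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
    return max(0.0, t1 - t0)
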