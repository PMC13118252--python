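"""Projector pair, masks, and geometry containers."""

import numpy as np
import pytest

from vmatct.geometry import (ConeBeamGeometry, DetectorMaskSet, GeometryError,
                             ProjectionSet, Volume3D, VolumeMask,
                             apply_detector_masks, back_project,
                             back_project_view, forward_project,
                             make_volume_mask)
from vmatct._projector import view_vectors

from conftest import ray_box_chord


def test_geometry_validation():
    with pytest.raises(GeometryError):
        ConeBeamGeometry(source_to_axis_distance_mm=-1.0)
    with pytest.raises(GeometryError):
        ConeBeamGeometry(source_to_axis_distance_mm=1600.0,
                         source_to_detector_distance_mm=1000.0)
    geo = ConeBeamGeometry()
    assert geo.magnification == pytest.approx(1.6)


def test_forward_zero_volume_and_linearity(tiny_geometry):
    rng = np.random.default_rng(0)
    zero = Volume3D.zeros(tiny_geometry)
    p = forward_project(zero, tiny_geometry, [0.0, 45.0, -90.0])
    assert np.all(p.images == 0.0)

    vol = Volume3D(rng.normal(size=tiny_geometry.volume_shape),
                   tiny_geometry.voxel_size_mm)
    p1 = forward_project(vol, tiny_geometry, [10.0, 100.0])
    vol2 = Volume3D(2.0 * vol.values, tiny_geometry.voxel_size_mm)
    p2 = forward_project(vol2, tiny_geometry, [10.0, 100.0])
    np.testing.assert_allclose(p2.images, 2.0 * p1.images, rtol=1e-12)


@pytest.mark.parametrize("angle", [0.0, 37.0])
def test_forward_uniform_cube_matches_chord_oracle(angle):
    """Line integral through a unit cube equals the analytic chord length."""
    geo = ConeBeamGeometry(volume_shape=(32, 32, 32), voxel_size_mm=2.0,
                           detector_rows=33, detector_cols=33,
                           detector_pixel_pitch_mm=2.0)
    half = 20.0  # cube of side 40 mm, faces midway between voxel centers
    c = (np.arange(32) - 15.5) * 2.0
    inside = np.abs(c) < half
    vals = np.zeros((32, 32, 32))
    vals[np.ix_(inside, inside, inside)] = 1.0
    p = forward_project(Volume3D(vals, 2.0), geo, [angle])

    src, det_c, u_hat, v_hat = view_vectors(
        angle, geo.source_to_axis_distance_mm,
        geo.source_to_detector_distance_mm)
    for iu, iv in [(16, 16), (14, 16), (16, 13)]:
        du = (iu - 16) * geo.detector_pixel_pitch_mm
        dv = (iv - 16) * geo.detector_pixel_pitch_mm
        pix = det_c + du * u_hat + dv * v_hat
        chord = ray_box_chord(src, pix - src, [-half] * 3, [half] * 3)
        assert p.images[0, iu, iv] == pytest.approx(chord, rel=0.02, abs=0.5)


def test_back_project_zero(tiny_geometry):
    p = ProjectionSet(np.zeros((3,) + tiny_geometry.detector_shape),
                      [0.0, 10.0, 20.0])
    vol = back_project(p, tiny_geometry)
    assert np.all(vol.values == 0.0)


def test_adjoint_identity_against_dense_matrix(small_geometry, dense_R_small):
    """<Rx, y> == <x, R^T y> verified against the materialized operator."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=small_geometry.volume_shape)
    y = rng.normal(size=small_geometry.detector_shape)
    angle = 42.0  # must match the dense fixture
    Rx = forward_project(Volume3D(x, small_geometry.voxel_size_mm),
                         small_geometry, [angle]).images[0]
    Rty = back_project_view(y, small_geometry, angle)
    lhs = float(np.sum(Rx * y))
    rhs = float(np.sum(x * Rty))
    assert lhs == pytest.approx(rhs, rel=1e-5)
    # and both agree with the dense operator
    np.testing.assert_allclose(Rx.ravel(), dense_R_small @ x.ravel(),
                               rtol=1e-8, atol=1e-10)
    np.testing.assert_allclose(Rty.ravel(), dense_R_small.T @ y.ravel(),
                               rtol=1e-8, atol=1e-10)


def test_single_pixel_backprojects_along_its_ray(tiny_geometry):
    """A lone detector pixel only touches voxels near its ray."""
    img = np.zeros(tiny_geometry.detector_shape)
    img[5, 7] = 1.0
    angle = 25.0
    vol = back_project_view(img, tiny_geometry, angle)
    src, det_c, u_hat, v_hat = view_vectors(
        angle, tiny_geometry.source_to_axis_distance_mm,
        tiny_geometry.source_to_detector_distance_mm)
    du = (5 - 5.5) * tiny_geometry.detector_pixel_pitch_mm
    dv = (7 - 5.5) * tiny_geometry.detector_pixel_pitch_mm
    pix = det_c + du * u_hat + dv * v_hat
    d = (pix - src) / np.linalg.norm(pix - src)
    origin = tiny_geometry.default_origin()
    nz = np.argwhere(vol != 0.0)
    assert nz.size > 0
    for idx in nz:
        pos = origin + idx * tiny_geometry.voxel_size_mm
        rel = pos - src
        dist = np.linalg.norm(rel - (rel @ d) * d)
        assert dist <= 2.0 * tiny_geometry.voxel_size_mm


def test_geometry_scaling_similarity():
    """Scaling every length by s scales all projections by s exactly."""
    rng = np.random.default_rng(5)
    vals = rng.random((12, 12, 12))
    p = {}
    for s in (1.0, 2.0):
        geo = ConeBeamGeometry(
            source_to_axis_distance_mm=500.0 * s,
            source_to_detector_distance_mm=800.0 * s,
            detector_rows=16, detector_cols=16,
            detector_pixel_pitch_mm=4.0 * s,
            volume_shape=(12, 12, 12), voxel_size_mm=3.0 * s)
        p[s] = forward_project(Volume3D(vals, geo.voxel_size_mm), geo,
                               [15.0, 200.0]).images
    np.testing.assert_allclose(p[2.0], 2.0 * p[1.0], rtol=1e-10)


def test_forward_errors(tiny_geometry):
    vol = Volume3D(np.zeros((4, 4, 4)), 4.0)
    with pytest.raises(GeometryError):
        forward_project(vol, tiny_geometry, [0.0])
    ok = Volume3D.zeros(tiny_geometry)
    with pytest.raises(GeometryError):
        forward_project(ok, tiny_geometry, [])


def test_make_volume_mask_conventions(tiny_geometry):
    full = make_volume_mask(tiny_geometry, (0, 0, 0), (1e4, 1e4, 1e4), 0.0)
    assert full.mask.all()
    assert full.n_voxels == np.prod(tiny_geometry.volume_shape)

    # zero-size box, margin m: voxel centers within +-m of the center
    m = 6.0  # 1.5 voxels of 4 mm -> 3 centers per axis (at -4, 0, +4)...
    geo = ConeBeamGeometry(volume_shape=(9, 9, 9), voxel_size_mm=4.0,
                           detector_rows=12, detector_cols=12,
                           detector_pixel_pitch_mm=6.0)
    mask = make_volume_mask(geo, (0, 0, 0), (0, 0, 0), m)
    # centers at 0, +-4 are within 6 mm -> cube of 3 voxels per side
    assert mask.mask.sum() == 27
    assert len(mask.voi_indices) == mask.mask.sum()

    with pytest.raises(GeometryError):
        make_volume_mask(tiny_geometry, (1e5, 0, 0), (1, 1, 1), 0.0)


def test_apply_detector_masks(tiny_geometry):
    rng = np.random.default_rng(11)
    images = rng.random((2,) + tiny_geometry.detector_shape)
    p = ProjectionSet(images, [0.0, 90.0])
    all_true = DetectorMaskSet.all_true(2, tiny_geometry.detector_shape)
    np.testing.assert_array_equal(
        apply_detector_masks(p, all_true).images, images)

    all_false = DetectorMaskSet(np.zeros_like(all_true.masks))
    assert np.all(apply_detector_masks(p, all_false).images == 0.0)

    checker = np.indices(tiny_geometry.detector_shape).sum(axis=0) % 2 == 0
    masks = DetectorMaskSet(np.stack([checker, ~checker]))
    out = apply_detector_masks(p, masks).images
    assert np.all(out[0][~checker] == 0.0)
    np.testing.assert_array_equal(out[0][checker], images[0][checker])
    np.testing.assert_array_equal(out[1][~checker], images[1][~checker])


def test_container_invariants():
    with pytest.raises(GeometryError):
        ProjectionSet(np.zeros((2, 4, 4)), [0.0])  # count mismatch
    with pytest.raises(GeometryError):
        VolumeMask(np.zeros((4, 4, 4), dtype=bool))  # empty
    with pytest.raises(GeometryError):
        Volume3D(np.full((4, 4, 4), np.nan), 1.0)  # non-finite
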