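"""Cone-beam geometry, domain containers, and the matched projector pair.

Conventions
-----------
* World coordinates in mm: x lateral, y vertical, z axial; the isocenter is
  the origin of world space and, by default, the geometric center of the
  reconstruction volume.
* Gantry angles in degrees; at 0 degrees the source sits above the
  isocenter at ``(0, SAD, 0)`` and positive angles rotate the source toward
  +x (clockwise as seen from the couch).
* Detector images are ``(n_u, n_v)`` arrays: axis 0 is the transverse u
  direction (the direction the gantry rotation sweeps), axis 1 the axial v
  direction.  The detector (u, v) origin is the detector center.
* ``back_project`` is the exact adjoint of ``forward_project`` with respect
  to the standard (unweighted) inner products on voxel and detector arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _projector

__all__ = [
    "ConeBeamGeometry",
    "Volume3D",
    "ProjectionSet",
    "DetectorMaskSet",
    "VolumeMask",
    "GeometryError",
    "forward_project",
    "back_project",
    "forward_project_view",
    "back_project_view",
    "make_volume_mask",
    "apply_detector_masks",
]


class GeometryError(ValueError):
    """Raised for inconsistent geometry / container configurations."""


@dataclass(frozen=True)
class ConeBeamGeometry:
    """Circular cone-beam layout: linac source, flat panel, voxel grid.

    Defaults are desk scale: a 64**3 volume of 2 mm voxels viewed by a
    96 x 96 panel of 2.5 mm pixels at SAD 1000 mm / SDD 1600 mm
    (magnification 1.6).  The clinical-scale grid (270 x 270 x 263 mm at
    1 mm voxels, 0.8 mm pixels, SDD 1600 mm) is supported by passing the
    corresponding values.
    """

    source_to_axis_distance_mm: float = 1000.0
    source_to_detector_distance_mm: float = 1600.0
    detector_rows: int = 96  # number of u (transverse) samples
    detector_cols: int = 96  # number of v (axial) samples
    detector_pixel_pitch_mm: float = 2.5
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0

    def __post_init__(self):
        if self.source_to_axis_distance_mm <= 0 or self.voxel_size_mm <= 0 \
                or self.detector_pixel_pitch_mm <= 0:
            raise GeometryError("all geometry lengths must be positive")
        if self.source_to_detector_distance_mm <= self.source_to_axis_distance_mm:
            raise GeometryError("SDD must exceed SAD (magnification > 1)")
        if min(self.volume_shape) < 1 or self.detector_rows < 1 or self.detector_cols < 1:
            raise GeometryError("grid shapes must be positive")

    @property
    def magnification(self) -> float:
        return self.source_to_detector_distance_mm / self.source_to_axis_distance_mm

    @property
    def detector_shape(self) -> tuple[int, int]:
        return (self.detector_rows, self.detector_cols)

    def default_origin(self) -> np.ndarray:
        """World position of voxel (0,0,0)'s center, isocenter-centered."""
        n = np.asarray(self.volume_shape, dtype=float)
        return -(n - 1) / 2.0 * self.voxel_size_mm

    def sampling_step_mm(self) -> float:
        """Ray sampling step: half a voxel."""
        return 0.5 * self.voxel_size_mm


@dataclass
class Volume3D:
    """Scalar attenuation field f on a regular isotropic voxel grid."""

    values: np.ndarray
    voxel_size_mm: float
    origin_mm: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GeometryError("volume must be a 3D array")
        if not np.all(np.isfinite(self.values)):
            raise GeometryError("volume values must be finite")
        if self.origin_mm is None:
            n = np.asarray(self.values.shape, dtype=float)
            self.origin_mm = -(n - 1) / 2.0 * self.voxel_size_mm
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)

    @classmethod
    def zeros(cls, geometry: ConeBeamGeometry) -> "Volume3D":
        return cls(np.zeros(geometry.volume_shape), geometry.voxel_size_mm)

    def copy(self) -> "Volume3D":
        return Volume3D(self.values.copy(), self.voxel_size_mm, self.origin_mm.copy())

    def voxel_centers(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin_mm[axis] + np.arange(n) * self.voxel_size_mm


@dataclass
class DetectorMaskSet:
    """Per-view boolean detector masks M_theta (aperture footprints)."""

    masks: np.ndarray

    def __post_init__(self):
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3:
            raise GeometryError("masks must be a (n_views, n_u, n_v) stack")

    @classmethod
    def all_true(cls, n_views: int, detector_shape: tuple[int, int]) -> "DetectorMaskSet":
        return cls(np.ones((n_views,) + tuple(detector_shape), dtype=bool))


@dataclass
class ProjectionSet:
    """Stack of portal images p with per-view gantry angles and masks."""

    images: np.ndarray
    gantry_angles_deg: np.ndarray
    masks: DetectorMaskSet | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=float)
        self.gantry_angles_deg = np.atleast_1d(
            np.asarray(self.gantry_angles_deg, dtype=float))
        if self.images.ndim != 3:
            raise GeometryError("images must be a (n_views, n_u, n_v) stack")
        if self.images.shape[0] != self.gantry_angles_deg.shape[0]:
            raise GeometryError("image count must equal angle count")
        if not np.all(np.isfinite(self.gantry_angles_deg)):
            raise GeometryError("gantry angles must be finite")
        if self.masks is not None and self.masks.masks.shape != self.images.shape:
            raise GeometryError("mask stack must match image stack shape")

    @property
    def n_views(self) -> int:
        return self.images.shape[0]

    def check_geometry(self, geometry: ConeBeamGeometry) -> None:
        if self.images.shape[1:] != geometry.detector_shape:
            raise GeometryError(
                f"projection shape {self.images.shape[1:]} does not match "
                f"detector shape {geometry.detector_shape}")


@dataclass
class VolumeMask:
    """Boolean reconstruction mask I (the volume of interest)."""

    mask: np.ndarray
    voi_indices: np.ndarray = field(default=None)  # (n_voi, 3) int array

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise GeometryError("volume mask must be 3D")
        if not self.mask.any():
            raise GeometryError("volume mask is empty")
        if self.voi_indices is None:
            self.voi_indices = np.argwhere(self.mask)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _check_volume(volume: Volume3D, geometry: ConeBeamGeometry) -> None:
    if volume.values.shape != tuple(geometry.volume_shape):
        raise GeometryError(
            f"volume shape {volume.values.shape} does not match geometry "
            f"{geometry.volume_shape}")


def forward_project_view(values: np.ndarray, geometry: ConeBeamGeometry,
                         angle_deg: float,
                         origin_mm: np.ndarray | None = None) -> np.ndarray:
    """Line integrals of a raw voxel array for a single gantry angle."""
    values = np.ascontiguousarray(values, dtype=float)
    if origin_mm is None:
        origin_mm = geometry.default_origin()
    src, det_c, u_hat, v_hat = _projector.view_vectors(
        angle_deg, geometry.source_to_axis_distance_mm,
        geometry.source_to_detector_distance_mm)
    return _projector.forward_view(
        values, geometry.voxel_size_mm,
        origin_mm[0], origin_mm[1], origin_mm[2],
        src, det_c, u_hat, v_hat,
        geometry.detector_rows, geometry.detector_cols,
        geometry.detector_pixel_pitch_mm, geometry.sampling_step_mm())


def back_project_view(image: np.ndarray, geometry: ConeBeamGeometry,
                      angle_deg: float,
                      origin_mm: np.ndarray | None = None) -> np.ndarray:
    """Adjoint of :func:`forward_project_view` for a single view."""
    image = np.ascontiguousarray(image, dtype=float)
    if image.shape != geometry.detector_shape:
        raise GeometryError("image shape does not match detector shape")
    if origin_mm is None:
        origin_mm = geometry.default_origin()
    src, det_c, u_hat, v_hat = _projector.view_vectors(
        angle_deg, geometry.source_to_axis_distance_mm,
        geometry.source_to_detector_distance_mm)
    return _projector.back_view(
        image, tuple(geometry.volume_shape), geometry.voxel_size_mm,
        origin_mm[0], origin_mm[1], origin_mm[2],
        src, det_c, u_hat, v_hat,
        geometry.detector_pixel_pitch_mm, geometry.sampling_step_mm())


def forward_project(volume: Volume3D, geometry: ConeBeamGeometry,
                    angles_deg) -> ProjectionSet:
    """Cone-beam forward projection R f at the given gantry angles."""
    _check_volume(volume, geometry)
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise GeometryError("angle list is empty")
    if not np.all(np.isfinite(angles)):
        raise GeometryError("angles must be finite")
    images = np.empty((angles.size,) + geometry.detector_shape)
    for i, a in enumerate(angles):
        images[i] = forward_project_view(volume.values, geometry, a,
                                         volume.origin_mm)
    return ProjectionSet(images, angles)


def back_project(projections: ProjectionSet,
                 geometry: ConeBeamGeometry) -> Volume3D:
    """Adjoint R^T of :func:`forward_project`, summed over all views."""
    projections.check_geometry(geometry)
    out = np.zeros(geometry.volume_shape)
    for img, a in zip(projections.images, projections.gantry_angles_deg):
        out += back_project_view(img, geometry, a)
    return Volume3D(out, geometry.voxel_size_mm)


def make_volume_mask(geometry: ConeBeamGeometry, target_center_mm,
                     target_halfwidths_mm, margin_mm: float) -> VolumeMask:
    """Axis-aligned box mask around a target, dilated by ``margin_mm``.

    A voxel belongs to the mask when its center lies inside the closed
    interval ``[c - h - margin, c + h + margin]`` on every axis.
    """
    center = np.asarray(target_center_mm, dtype=float)
    half = np.asarray(target_halfwidths_mm, dtype=float)
    if np.any(half < 0) or margin_mm < 0:
        raise GeometryError("halfwidths and margin must be non-negative")
    origin = geometry.default_origin()
    mask = np.ones(geometry.volume_shape, dtype=bool)
    for ax in range(3):
        centers = origin[ax] + np.arange(geometry.volume_shape[ax]) * geometry.voxel_size_mm
        inside = np.abs(centers - center[ax]) <= half[ax] + margin_mm + 1e-9
        shape = [1, 1, 1]
        shape[ax] = -1
        mask &= inside.reshape(shape)
    if not mask.any():
        raise GeometryError("mask box does not intersect the volume grid")
    return VolumeMask(mask)


def apply_detector_masks(projections: ProjectionSet,
                         masks: DetectorMaskSet) -> ProjectionSet:
    """Zero detector pixels outside each view's mask M_theta."""
    if masks.masks.shape != projections.images.shape:
        raise GeometryError("mask stack does not match projection stack")
    return ProjectionSet(projections.images * masks.masks,
                         projections.gantry_angles_deg.copy(), masks)
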