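"""Synthetic chest phantom and VMAT acquisition simulator.

Real inputs to this reconstruction problem are megavoltage portal images
captured by the EPID during an arc delivery: the gantry sweeps a limited
arc, and at each angle only the MLC aperture around the target is exposed,
so every projection is laterally truncated.  No public dataset of this
kind exists, so the package ships a generator that emulates the regime:

* a chest-like digital phantom (soft-tissue body ellipsoid, two lungs, a
  spine cylinder, a target sphere containing an air cavity) rasterized
  without anti-aliasing, so the clean phantom contains exactly the
  declared intensity levels;
* an arc acquisition with uniformly spaced gantry angles, a per-view
  rectangular aperture that tracks the target's projected centroid
  (a deliberate simplification of MLC leaf sequences), and optional
  Gaussian or Poisson noise inside the aperture.

All randomness flows from the single seed in :class:`AcquisitionSpec`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import (ConeBeamGeometry, DetectorMaskSet, GeometryError,
                       ProjectionSet, Volume3D, VolumeMask, forward_project,
                       make_volume_mask)
from .metrics import EvaluationBoxes

__all__ = ["PhantomSpec", "AcquisitionSpec", "NoiseSpec", "ApertureSpec",
           "make_phantom", "simulate_vmat_acquisition"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and intensities of the digital chest phantom (mm, a.u.).

    Intensities are relative attenuation in HU-like arbitrary units
    (air 0, lung 25, soft tissue 100, target 120, bone 200); the scale is
    chosen commensurate with clinical CT image magnitudes because the
    reconstruction's shrinkage thresholds (1/alpha, 1/beta) are absolute
    intensity quantities.  The target sphere holds a concentric air cavity
    large enough to contain a 1 cm^3 evaluation box clear of the cavity
    wall.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    body_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_semiaxes: tuple[float, float, float] = (60.0, 45.0, 60.0)
    lung_offset: tuple[float, float, float] = (36.0, 0.0, 0.0)  # mirrored in x
    lung_semiaxes: tuple[float, float, float] = (14.0, 22.0, 40.0)
    spine_center_xy: tuple[float, float] = (0.0, -30.0)
    spine_radius: float = 8.0
    target_center: tuple[float, float, float] = (0.0, 8.0, 0.0)
    target_radius: float = 17.0
    cavity_radius: float = 12.0
    intensity_air: float = 0.0
    intensity_lung: float = 25.0
    intensity_soft: float = 100.0
    intensity_target: float = 120.0
    intensity_bone: float = 200.0
    mask_margin_mm: float = 10.0
    ref_box_center: tuple[float, float, float] = (0.0, 8.0, 22.0)
    eval_box_halfwidth_mm: float = 5.0  # 1 cm cubes

    def __post_init__(self):
        if not (self.intensity_air < self.intensity_soft < self.intensity_bone):
            raise ValueError("intensities must satisfy air < soft < bone")
        if min(self.intensity_air, self.intensity_lung,
               self.intensity_soft, self.intensity_target,
               self.intensity_bone) < 0:
            raise ValueError("intensities must be non-negative")
        if self.cavity_radius >= self.target_radius:
            raise ValueError("cavity must fit inside the target sphere")


def _grids(spec: PhantomSpec):
    n = np.asarray(spec.shape, dtype=float)
    origin = -(n - 1) / 2.0 * spec.voxel_size_mm
    ax = [origin[a] + np.arange(spec.shape[a]) * spec.voxel_size_mm
          for a in range(3)]
    return np.meshgrid(*ax, indexing="ij")


def _ellipsoid(x, y, z, center, semi):
    return ((x - center[0]) / semi[0]) ** 2 + \
           ((y - center[1]) / semi[1]) ** 2 + \
           ((z - center[2]) / semi[2]) ** 2 <= 1.0


def _box_indices(spec: PhantomSpec, center_mm, halfwidth_mm):
    """Index bounds (lo inclusive, hi exclusive) of a cube of voxel centers.

    The box is an odd-count cube of voxels spanning ``2 * halfwidth_mm``
    (5 voxels of 2 mm for the default 1 cm cube), centered on the voxel
    whose center is nearest ``center_mm``.
    """
    n = np.asarray(spec.shape, dtype=float)
    origin = -(n - 1) / 2.0 * spec.voxel_size_mm
    half_count = int(np.floor(halfwidth_mm / spec.voxel_size_mm))
    lo, hi = [], []
    for a in range(3):
        c = int(np.round((center_mm[a] - origin[a]) / spec.voxel_size_mm))
        l, h = c - half_count, c + half_count + 1
        if l < 0 or h > spec.shape[a]:
            raise ValueError("evaluation box extends outside the grid")
        lo.append(l)
        hi.append(h)
    return tuple(lo), tuple(hi)


def make_phantom(spec: PhantomSpec = PhantomSpec(),
                 geometry: ConeBeamGeometry | None = None
                 ) -> tuple[Volume3D, VolumeMask, EvaluationBoxes]:
    """Rasterize the phantom; return it with its target mask and boxes.

    The target mask is the target bounding box dilated by
    ``mask_margin_mm``.  The VOI box sits inside the air cavity and the
    reference box in uniform soft tissue; on the *clean* phantom the
    reference box has zero variance, so CNR is well defined only on
    reconstructions or otherwise noisy volumes.
    """
    x, y, z = _grids(spec)
    vol = np.full(spec.shape, spec.intensity_air, dtype=float)
    body = _ellipsoid(x, y, z, spec.body_center, spec.body_semiaxes)
    vol[body] = spec.intensity_soft
    for sgn in (+1.0, -1.0):
        c = (sgn * spec.lung_offset[0], spec.lung_offset[1], spec.lung_offset[2])
        lung = _ellipsoid(x, y, z, c, spec.lung_semiaxes) & body
        vol[lung] = spec.intensity_lung
    spine = (((x - spec.spine_center_xy[0]) ** 2 +
              (y - spec.spine_center_xy[1]) ** 2)
             <= spec.spine_radius ** 2) & body
    vol[spine] = spec.intensity_bone
    tc = spec.target_center
    r2 = (x - tc[0]) ** 2 + (y - tc[1]) ** 2 + (z - tc[2]) ** 2
    target = (r2 <= spec.target_radius ** 2) & body
    vol[target] = spec.intensity_target
    cavity = r2 <= spec.cavity_radius ** 2
    vol[cavity & body] = spec.intensity_air
    if not body.any() or not target.any():
        raise ValueError("phantom structures fall outside the grid")

    if geometry is None:
        geometry = ConeBeamGeometry(volume_shape=tuple(spec.shape),
                                    voxel_size_mm=spec.voxel_size_mm)
    hw = (spec.target_radius,) * 3
    mask = make_volume_mask(geometry, tc, hw, spec.mask_margin_mm)

    voi_lo, voi_hi = _box_indices(spec, tc, spec.eval_box_halfwidth_mm)
    ref_lo, ref_hi = _box_indices(spec, spec.ref_box_center,
                                  spec.eval_box_halfwidth_mm)
    boxes = EvaluationBoxes(voi_lo, voi_hi, ref_lo, ref_hi)
    volume = Volume3D(vol, spec.voxel_size_mm)
    return volume, mask, boxes


@dataclass(frozen=True)
class NoiseSpec:
    """Projection-domain noise: 'none', 'gaussian' (sigma) or 'poisson'."""

    kind: str = "gaussian"
    sigma: float = 2.0      # 2% of soft tissue; units of intensity * mm
    poisson_scale: float = 100.0

    def __post_init__(self):
        if self.kind not in ("none", "gaussian", "poisson"):
            raise ValueError("noise kind must be none|gaussian|poisson")
        if self.sigma < 0 or self.poisson_scale <= 0:
            raise ValueError("invalid noise parameters")


@dataclass(frozen=True)
class ApertureSpec:
    """Per-view rectangle tracking the target's projected centroid."""

    target_center_mm: tuple[float, float, float] = (0.0, 8.0, 0.0)
    target_halfwidths_mm: tuple[float, float, float] = (17.0, 17.0, 17.0)
    margin_mm: float = 10.0

    def __post_init__(self):
        if self.margin_mm < 0:
            raise ValueError("aperture margin must be non-negative")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Arc-limited, aperture-truncated acquisition; defaults are the
    standard scene: arc [-175, 175] degrees, 120 views, 10 mm aperture
    margin, Gaussian noise sigma 2.0 (2% of the soft-tissue intensity),
    seed 1."""

    arc_start_deg: float = -175.0
    arc_stop_deg: float = 175.0
    n_views: int = 120
    aperture: ApertureSpec = field(default_factory=ApertureSpec)
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    seed: int = 1

    def __post_init__(self):
        if not (-180.0 <= self.arc_start_deg < self.arc_stop_deg <= 180.0):
            raise ValueError("arc range must lie within [-180, 180]")
        if self.n_views < 2:
            raise ValueError("need at least two views")

    def angles(self) -> np.ndarray:
        return np.linspace(self.arc_start_deg, self.arc_stop_deg, self.n_views)


def _aperture_mask(geometry: ConeBeamGeometry, angle_deg: float,
                   ap: ApertureSpec) -> np.ndarray:
    """Rectangular detector mask around the projected target centroid."""
    t = np.deg2rad(angle_deg)
    e = np.array([np.sin(t), np.cos(t), 0.0])
    u_hat = np.array([np.cos(t), -np.sin(t), 0.0])
    c = np.asarray(ap.target_center_mm, dtype=float)
    sad = geometry.source_to_axis_distance_mm
    sdd = geometry.source_to_detector_distance_mm
    depth = sad - float(c @ e)          # distance source -> target plane
    if depth <= 0:
        raise GeometryError("target behind the source")
    mag = sdd / depth
    u_c = float(c @ u_hat) * mag
    v_c = c[2] * mag
    hx, hy, hz = ap.target_halfwidths_mm
    hu = (max(hx, hy) + ap.margin_mm) * mag
    hv = (hz + ap.margin_mm) * mag
    pitch = geometry.detector_pixel_pitch_mm
    nu, nv = geometry.detector_shape
    u = (np.arange(nu) - (nu - 1) / 2.0) * pitch
    v = (np.arange(nv) - (nv - 1) / 2.0) * pitch
    mask = (np.abs(u - u_c)[:, None] <= hu) & (np.abs(v - v_c)[None, :] <= hv)
    if not mask.any():
        raise GeometryError(
            f"aperture misses the detector at angle {angle_deg:g} deg")
    return mask


def simulate_vmat_acquisition(phantom: Volume3D, geometry: ConeBeamGeometry,
                              acq: AcquisitionSpec = AcquisitionSpec()
                              ) -> tuple[ProjectionSet, DetectorMaskSet]:
    """Forward-project the phantom over the arc and truncate per view.

    Outside each view's aperture both the signal and the mask are zeroed;
    noise is applied only inside the aperture, drawn from a generator
    seeded by ``acq.seed``.
    """
    angles = acq.angles()
    clean = forward_project(phantom, geometry, angles)
    masks = np.stack([_aperture_mask(geometry, a, acq.aperture)
                      for a in angles])
    rng = np.random.default_rng(acq.seed)
    images = clean.images * masks
    if acq.noise.kind == "gaussian" and acq.noise.sigma > 0:
        noise = rng.normal(0.0, acq.noise.sigma, size=images.shape)
        images = images + noise * masks
    elif acq.noise.kind == "poisson":
        s = acq.noise.poisson_scale
        noisy = rng.poisson(np.maximum(images, 0.0) * s) / s
        images = np.where(masks, noisy, 0.0)
    mask_set = DetectorMaskSet(masks)
    return ProjectionSet(images, angles, mask_set), mask_set
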