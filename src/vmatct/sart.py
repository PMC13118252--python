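"""Modified SART sweep minimizing the locally filtered fidelity term.

One sweep visits every gantry angle in ascending order and applies

    x <- x + I . lambda V^-1 R^T W (p_L - (R x)_L),   restricted to M_theta

where I is the reconstruction-volume mask, M_theta the per-view detector
mask, W the reciprocal in-mask ray sums (row normalization) and V the
in-mask ray-coverage per voxel (column normalization).  Negative voxels are
clipped to zero once per sweep, after the last view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import (ConeBeamGeometry, DetectorMaskSet, GeometryError,
                       ProjectionSet, Volume3D, VolumeMask,
                       back_project_view, forward_project_view)
from .local_filter import LocalFilterKernel, local_filter_image

__all__ = ["SartWeights", "compute_sart_weights", "sart_sweep",
           "precompute_sart_weights"]

logger = logging.getLogger(__name__)

# Rays whose in-mask path length is shorter than this fraction of a voxel
# are inactive: a grazing ray carries no reliable VOI information but its
# reciprocal weight W would be enormous.  Voxels with coverage V below
# _EPS_VOX receive no update at a view.
_EPS_RAY_VOXELS = 0.5
_EPS_VOX = 1e-9


@dataclass
class SartWeights:
    """Per-view SART normalization: voxel coverage V, ray weights W."""

    V: np.ndarray            # volume-shaped column sums over active rays
    W: np.ndarray            # detector-shaped reciprocal row sums (0 if inactive)
    active: np.ndarray       # detector-shaped bool: usable rays
    relaxation: float = 1.0

    def __post_init__(self):
        if self.relaxation <= 0:
            raise ValueError("relaxation must be positive")


def compute_sart_weights(geometry: ConeBeamGeometry, angle_deg: float,
                         volume_mask: VolumeMask,
                         detector_mask: np.ndarray,
                         relaxation: float = 1.0) -> SartWeights:
    """Row/column normalization weights of the masked system at one view.

    W_mm is the reciprocal of the ray's path-length sum over in-mask voxels
    (forward projection of the VOI indicator); V_nn is the coverage each
    voxel receives from in-mask rays (back projection of the active-ray
    indicator).  Rays that never cross the VOI are flagged inactive.
    """
    detector_mask = np.asarray(detector_mask, dtype=bool)
    if detector_mask.shape != geometry.detector_shape:
        raise GeometryError("detector mask shape mismatch")
    if not detector_mask.any():
        raise GeometryError("detector mask is empty at this view")
    row_sums = forward_project_view(volume_mask.mask.astype(float),
                                    geometry, angle_deg)
    eps_ray = _EPS_RAY_VOXELS * geometry.voxel_size_mm
    active = detector_mask & (row_sums > eps_ray)
    if not active.any():
        raise GeometryError(
            f"no usable rays at gantry angle {angle_deg:g} deg")
    W = np.zeros_like(row_sums)
    W[active] = 1.0 / row_sums[active]
    V = back_project_view(active.astype(float), geometry, angle_deg)
    return SartWeights(V=V, W=W, active=active, relaxation=relaxation)


def precompute_sart_weights(geometry: ConeBeamGeometry, angles_deg,
                            volume_mask: VolumeMask,
                            detector_masks: DetectorMaskSet,
                            relaxation: float = 1.0) -> list:
    """Weights for every view; entries are None where a view is unusable."""
    out = []
    for i, a in enumerate(np.atleast_1d(angles_deg)):
        try:
            out.append(compute_sart_weights(
                geometry, float(a), volume_mask, detector_masks.masks[i],
                relaxation))
        except GeometryError as exc:
            logger.warning("skipping view %d (%.1f deg): %s", i, a, exc)
            out.append(None)
    if all(w is None for w in out):
        raise GeometryError("no usable views")
    return out


def sart_sweep(f: Volume3D, filtered_measured: ProjectionSet,
               geometry: ConeBeamGeometry, volume_mask: VolumeMask,
               detector_masks: DetectorMaskSet, kernel: LocalFilterKernel,
               relaxation: float = 1.0,
               weights: list | None = None) -> tuple[Volume3D, float]:
    """One full modified-SART pass over all views, ascending gantry angle.

    ``filtered_measured`` must already hold the locally filtered (and
    masked) measured projections p_L.  Returns the updated volume (with
    negatives clipped after the sweep) and the root-sum-square of the
    masked filtered residuals accumulated across views, for logging.
    """
    filtered_measured.check_geometry(geometry)
    if detector_masks.masks.shape != filtered_measured.images.shape:
        raise GeometryError("detector mask stack shape mismatch")
    if volume_mask.mask.shape != tuple(geometry.volume_shape):
        raise GeometryError("volume mask shape mismatch")
    angles = filtered_measured.gantry_angles_deg
    order = np.argsort(angles, kind="stable")
    if weights is None:
        weights = precompute_sart_weights(geometry, angles, volume_mask,
                                          detector_masks, relaxation)
    x = f.values.copy()
    mask = volume_mask.mask
    res_sq = 0.0
    for i in order:
        w = weights[i]
        if w is None:
            continue
        proj_l = local_filter_image(
            forward_project_view(x, geometry, float(angles[i]), f.origin_mm),
            kernel)
        dp = np.where(w.active,
                      filtered_measured.images[i] - proj_l, 0.0)
        res_sq += float(np.sum(dp * dp))
        bp = back_project_view(w.W * dp, geometry, float(angles[i]),
                               f.origin_mm)
        upd = np.zeros_like(x)
        ok = mask & (w.V > _EPS_VOX)
        upd[ok] = relaxation * bp[ok] / w.V[ok]
        x += upd
    np.maximum(x, 0.0, out=x)
    return Volume3D(x, f.voxel_size_mm, f.origin_mm.copy()), float(np.sqrt(res_sq))
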