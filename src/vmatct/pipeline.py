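"""Outer reconstruction loop and the FDK / lambda-tomography baseline.

The iterative reconstruction alternates a modified-SART fidelity sweep on
locally filtered projections with the split-Bregman TV+BM3D denoising
step, starting from a blank volume, until the normalized update ratio

    r_j = ||f_{j+1} - f_j|| / ||f_1||        (Frobenius norms)

falls below the stopping threshold (default 0.005) or the iteration count
reaches the maximum (default 20).

The baseline arm reconstructs the same data with a filtered-backprojection
pass in which the local lambda kernel replaces the ramp filter (lambda
tomography): cosine pre-weighting, per-row convolution along u,
short-scan (Parker/over-scan) angular weighting when the arc is shorter
than a full turn, and FDK distance-weighted backprojection.  The result is
edge-enhancing and non-quantitative, as lambda reconstructions are.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import _projector
from .denoise import BM3DParams, DenoiseConfig, tv_bm3d_denoise_step
from .geometry import (ConeBeamGeometry, DetectorMaskSet, GeometryError,
                       ProjectionSet, Volume3D, VolumeMask,
                       apply_detector_masks)
from .local_filter import (LocalFilterKernel, erode_detector_masks,
                           local_filter_image, local_filter_set)
from .sart import precompute_sart_weights, sart_sweep

__all__ = ["ReconConfig", "ConvergenceHistory", "update_ratio",
           "reconstruct_tv_bm3d", "reconstruct_fdk_lt"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ReconConfig:
    """All hyperparameters of the iterative reconstruction."""

    denoise: DenoiseConfig = field(default_factory=DenoiseConfig)
    bm3d: BM3DParams = field(default_factory=BM3DParams)
    kernel: LocalFilterKernel = field(default_factory=LocalFilterKernel)
    relaxation: float = 1.0
    stop_threshold: float = 0.005
    max_iterations: int = 20

    def __post_init__(self):
        if self.stop_threshold <= 0:
            raise ValueError("stop_threshold must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.relaxation <= 0:
            raise ValueError("relaxation must be positive")


@dataclass
class ConvergenceHistory:
    """Per-outer-iteration diagnostics of a reconstruction run."""

    iteration: list[int] = field(default_factory=list)
    update_ratio: list[float] = field(default_factory=list)
    residual_norm: list[float] = field(default_factory=list)
    wall_time_s: list[float] = field(default_factory=list)

    def append(self, j, r, res, dt):
        self.iteration.append(int(j))
        self.update_ratio.append(float(r))
        self.residual_norm.append(float(res))
        self.wall_time_s.append(float(dt))

    def __len__(self):
        return len(self.iteration)

    def to_records(self) -> list[dict]:
        return [
            {"iteration": j, "update_ratio": r, "residual_norm": res,
             "wall_time_s": t}
            for j, r, res, t in zip(self.iteration, self.update_ratio,
                                    self.residual_norm, self.wall_time_s)]


def update_ratio(f_next, f_curr, f_first) -> float:
    """Normalized update r_j = ||f_next - f_curr|| / ||f_first||.

    Returns NaN (the "undefined" sentinel, treated as converged by the
    outer loop) when the first iterate has zero norm.
    """
    a = f_next.values if isinstance(f_next, Volume3D) else np.asarray(f_next)
    b = f_curr.values if isinstance(f_curr, Volume3D) else np.asarray(f_curr)
    c = f_first.values if isinstance(f_first, Volume3D) else np.asarray(f_first)
    if a.shape != b.shape or a.shape != c.shape:
        raise ValueError("volumes must share a shape")
    denom = float(np.linalg.norm(c.ravel()))
    if denom == 0.0:
        return float("nan")
    return float(np.linalg.norm((a - b).ravel()) / denom)


def reconstruct_tv_bm3d(projections: ProjectionSet,
                        geometry: ConeBeamGeometry,
                        volume_mask: VolumeMask,
                        detector_masks: DetectorMaskSet | None = None,
                        cfg: ReconConfig = ReconConfig()
                        ) -> tuple[Volume3D, ConvergenceHistory]:
    """Iterative TV-BM3D reconstruction from truncated projections."""
    projections.check_geometry(geometry)
    if detector_masks is None:
        detector_masks = projections.masks
    if detector_masks is None:
        detector_masks = DetectorMaskSet.all_true(projections.n_views,
                                                  geometry.detector_shape)
    eff_masks = erode_detector_masks(detector_masks, cfg.kernel)
    # measured data are filtered (then masked) once; they never change
    p_l = apply_detector_masks(
        local_filter_set(projections, cfg.kernel), eff_masks)
    weights = precompute_sart_weights(geometry, projections.gantry_angles_deg,
                                      volume_mask, eff_masks, cfg.relaxation)
    f = Volume3D.zeros(geometry)
    f_first = None
    history = ConvergenceHistory()
    t_start = time.perf_counter()
    for j in range(1, cfg.max_iterations + 1):
        f_new, res = sart_sweep(f, p_l, geometry, volume_mask, eff_masks,
                                cfg.kernel, cfg.relaxation, weights)
        if cfg.denoise.inner_loops > 0:
            f_new = tv_bm3d_denoise_step(f_new, cfg.denoise, cfg.bm3d)
        if f_first is None:
            f_first = f_new.copy()
            r = float("nan")
            if float(np.linalg.norm(f_first.values.ravel())) == 0.0:
                logger.warning("first iterate is identically zero; "
                               "declaring convergence")
                history.append(j, r, res, time.perf_counter() - t_start)
                f = f_new
                break
        else:
            r = update_ratio(f_new, f, f_first)
        history.append(j, r, res, time.perf_counter() - t_start)
        logger.info("iteration %d: r_j=%s residual=%.4g", j, r, res)
        f = f_new
        if np.isfinite(r) and r < cfg.stop_threshold:
            break
    np.maximum(f.values, 0.0, out=f.values)
    return f, history


def _parker_weights(angles_rad: np.ndarray, fan_angles: np.ndarray
                    ) -> np.ndarray:
    """Smooth short-scan weights for an arc shorter than a full turn.

    The classic short-scan construction with over-scan half-angle
    delta = (arc - pi) / 2: redundantly measured rays at the two ends of
    the arc are blended with sin^2 ramps.  Returns an (n_views, n_u)
    array; a full 360-degree scan gets uniform weights 1/2.
    """
    arc = float(angles_rad.max() - angles_rad.min())
    n_views = angles_rad.size
    if arc >= 2.0 * np.pi - 1e-9:
        return np.full((n_views, fan_angles.size), 0.5)
    beta = angles_rad - angles_rad.min()
    delta = max((arc - np.pi) / 2.0, 1e-6)
    w = np.ones((n_views, fan_angles.size))
    g = fan_angles[None, :]
    b = beta[:, None]
    lo = 2.0 * (delta - g)
    with np.errstate(divide="ignore", invalid="ignore"):
        ramp_in = np.sin(np.pi / 4.0 * b / (delta - g)) ** 2
        ramp_out = np.sin(np.pi / 4.0 * (np.pi + 2.0 * delta - b)
                          / (delta + g)) ** 2
    w = np.where(b < lo, ramp_in, w)
    w = np.where(b > np.pi - 2.0 * g, ramp_out, w)
    return np.clip(np.nan_to_num(w, nan=0.0), 0.0, 1.0)


def reconstruct_fdk_lt(projections: ProjectionSet,
                       geometry: ConeBeamGeometry,
                       kernel: LocalFilterKernel = LocalFilterKernel()
                       ) -> Volume3D:
    """FDK-style backprojection with the local lambda kernel as filter."""
    projections.check_geometry(geometry)
    if projections.n_views < 2:
        raise GeometryError("FDK baseline needs at least two views")
    sad = geometry.source_to_axis_distance_mm
    sdd = geometry.source_to_detector_distance_mm
    pitch = geometry.detector_pixel_pitch_mm
    nu, nv = geometry.detector_shape
    u = (np.arange(nu) - (nu - 1) / 2.0) * pitch
    v = (np.arange(nv) - (nv - 1) / 2.0) * pitch
    cosw = sdd / np.sqrt(sdd ** 2 + u[:, None] ** 2 + v[None, :] ** 2)
    order = np.argsort(projections.gantry_angles_deg, kind="stable")
    angles = np.deg2rad(projections.gantry_angles_deg[order])
    fan = np.arctan(u / sdd)
    parker = _parker_weights(angles, fan)
    dbeta = float(np.mean(np.diff(angles))) if angles.size > 1 else 1.0
    origin = geometry.default_origin()
    out = np.zeros(geometry.volume_shape)
    for k, idx in enumerate(order):
        img = projections.images[idx] * cosw * parker[k][:, None]
        filt = local_filter_image(img, kernel)
        t = angles[k]
        out += _projector.fdk_back_view(
            np.ascontiguousarray(filt), tuple(geometry.volume_shape),
            geometry.voxel_size_mm, origin[0], origin[1], origin[2],
            sad, sdd, np.sin(t), np.cos(t), pitch, abs(dbeta))
    return Volume3D(out, geometry.voxel_size_mm)
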