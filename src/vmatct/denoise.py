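"""Split-Bregman TV + BM3D denoising of the reconstruction volume.

After each data-fidelity (SART) update the volume f_j is denoised by
solving

    min  |D_x|_1 + |D_y|_1 + |D_z|_1 + mu ||f - f_j||^2 + delta |D_w|_1
    s.t. D_x = grad_x f, D_y = grad_y f, D_z = grad_z f, D_w = BM3D(f)

with the split Bregman method: auxiliary variables are updated by soft
shrinkage (thresholds 1/alpha on the gradient channels, 1/beta on the BM3D
channel), Bregman multipliers accumulate the constraint violations, and
the quadratic f-subproblem

    (mu + alpha grad^T grad + beta I) f = mu f_j
        + alpha sum_a grad_a^T (D_a - b_a) + beta (D_w - b_w)

is diagonalized exactly by the 3D FFT because the finite differences are
periodic.  The BM3D constraint enters the quadratic solve through an
identity-operator approximation (the ``+ beta`` in the denominator); the
BM3D operator itself acts only in the D_w / b_w updates, once per loop.

Within each inner loop the auxiliary and multiplier updates use the volume
from the *previous* loop, then the f-subproblem is solved -- i.e. the loop
order is D/b update first, f update last.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from . import _bm3d
from .geometry import Volume3D

__all__ = [
    "DenoiseConfig",
    "BM3DParams",
    "BregmanState",
    "shrink",
    "gradient_ops",
    "transpose_gradient",
    "laplacian_spectrum",
    "total_variation",
    "estimate_noise_sigma",
    "bm3d_denoise",
    "solve_f_subproblem",
    "update_bregman",
    "tv_bm3d_denoise_step",
    "denoise_objective",
]


@dataclass(frozen=True)
class DenoiseConfig:
    """Weights of the denoising objective and the inner loop count.

    mu weighs proximity to the SART output, alpha/beta are the quadratic
    penalty weights of the gradient and BM3D constraints (the shrinkage
    thresholds are 1/alpha and 1/beta), delta weighs the BM3D L1 term in
    the objective.  delta is exposed but the shrinkage thresholds follow
    the update equations verbatim, which assume delta = 1.
    """

    mu: float = 2.0
    delta: float = 1.0
    alpha: float = 1.0
    beta: float = 0.3
    inner_loops: int = 10

    def __post_init__(self):
        if self.mu <= 0 or self.alpha <= 0 or self.beta <= 0:
            raise ValueError("mu, alpha and beta must be positive")
        if self.inner_loops < 0:
            raise ValueError("inner_loops must be >= 0")


@dataclass(frozen=True)
class BM3DParams:
    """Parameters of the slice-wise hard-thresholding BM3D operator."""

    block_size: int = 8
    search_radius: int = 16
    max_group: int = 16
    hard_threshold_multiplier: float = 2.7
    noise_sigma: float | None = None  # None: estimate per slice (MAD)
    ref_step: int = 4

    def __post_init__(self):
        if self.block_size < 4:
            raise ValueError("block_size must be >= 4")
        if self.search_radius < self.block_size:
            raise ValueError("search_radius must be >= block_size")
        g = self.max_group
        if g < 1 or (g & (g - 1)) != 0:
            raise ValueError("max_group must be a power of two")
        if self.hard_threshold_multiplier < 0:
            raise ValueError("hard_threshold_multiplier must be >= 0")
        if self.ref_step < 1:
            raise ValueError("ref_step must be >= 1")


@dataclass
class BregmanState:
    """Auxiliary variables and multipliers of the split-Bregman loop."""

    D_x: np.ndarray
    D_y: np.ndarray
    D_z: np.ndarray
    D_w: np.ndarray
    b_x: np.ndarray
    b_y: np.ndarray
    b_z: np.ndarray
    b_w: np.ndarray
    k: int = 0

    @classmethod
    def zeros(cls, shape) -> "BregmanState":
        return cls(*(np.zeros(shape) for _ in range(8)))


def shrink(x, sigma):
    """Elementwise soft threshold: the proximal map of sigma |.|_1."""
    if sigma < 0:
        raise ValueError("shrink threshold must be non-negative")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - sigma, 0.0)


def gradient_ops(f: np.ndarray):
    """Forward finite differences with periodic wrap, per axis."""
    return tuple(np.roll(f, -1, axis=a) - f for a in range(3))


def transpose_gradient(g: np.ndarray, axis: int) -> np.ndarray:
    """Exact adjoint of the periodic forward difference on one axis."""
    return np.roll(g, 1, axis=axis) - g


def laplacian_spectrum(shape) -> np.ndarray:
    """Eigenvalues of grad^T grad (periodic discrete Laplacian), rfft layout.

    Per axis the eigenvalues are 2 - 2 cos(2 pi k / n) >= 0; the full
    spectrum is their sum broadcast over the 3D (real-FFT) frequency grid.
    """
    nx, ny, nz = shape
    ex = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(nx))
    ey = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.fft.fftfreq(ny))
    ez = 2.0 - 2.0 * np.cos(2.0 * np.pi * np.fft.rfftfreq(nz))
    return (ex[:, None, None] + ey[None, :, None] + ez[None, None, :])


def total_variation(f: np.ndarray) -> float:
    """Anisotropic TV: sum of L1 norms of the three periodic gradients."""
    return float(sum(np.abs(g).sum() for g in gradient_ops(np.asarray(f, float))))


def estimate_noise_sigma(img: np.ndarray) -> float:
    """Robust noise sigma of a 2D slice from the finest diagonal detail.

    Median absolute value of the Haar diagonal detail coefficients divided
    by 0.6745 (the Gaussian consistency constant).
    """
    img = np.asarray(img, dtype=float)
    nx, ny = (s - s % 2 for s in img.shape)
    a = img[0:nx:2, 0:ny:2]
    b = img[1:nx:2, 0:ny:2]
    c = img[0:nx:2, 1:ny:2]
    d = img[1:nx:2, 1:ny:2]
    diag = (a - b - c + d) / 2.0
    return float(np.median(np.abs(diag)) / 0.6745)


def _as_array(f) -> np.ndarray:
    return f.values if isinstance(f, Volume3D) else np.asarray(f, dtype=float)


def bm3d_denoise(f, params: BM3DParams = BM3DParams()):
    """Slice-wise BM3D over the axial (x, y) planes of a volume.

    Each z slice is denoised independently: block matching within a local
    search window, stacking of up to ``max_group`` similar blocks, a
    separable orthonormal 3D transform, hard thresholding at
    ``hard_threshold_multiplier * sigma`` and weighted aggregation.  With
    ``noise_sigma=None`` sigma is estimated per slice; constant inputs are
    reproduced exactly.
    """
    arr = _as_array(f)
    if arr.ndim != 3:
        raise ValueError("expected a 3D volume")
    if min(arr.shape[:2]) < params.block_size:
        raise ValueError("slice smaller than the BM3D block size")
    D2 = _bm3d.dct_matrix(params.block_size)
    D1 = _bm3d.dct_stack_matrices(params.max_group)
    out = np.empty_like(arr)
    for k in range(arr.shape[2]):
        sl = np.ascontiguousarray(arr[:, :, k])
        sigma = (params.noise_sigma if params.noise_sigma is not None
                 else estimate_noise_sigma(sl))
        out[:, :, k] = _bm3d.bm3d_slice(
            sl, sigma, params.block_size, params.search_radius,
            params.max_group, params.hard_threshold_multiplier,
            params.ref_step, D2, D1)
    if isinstance(f, Volume3D):
        return Volume3D(out, f.voxel_size_mm, f.origin_mm.copy())
    return out


def solve_f_subproblem(f_j, state: BregmanState,
                       cfg: DenoiseConfig = DenoiseConfig()):
    """FFT solve of the quadratic f-subproblem.

    Solves (mu + alpha grad^T grad + beta) f = rhs exactly in the Fourier
    domain; the output is real by conjugate symmetry.
    """
    arr = _as_array(f_j)
    rhs = cfg.mu * arr
    rhs = rhs + cfg.alpha * (
        transpose_gradient(state.D_x - state.b_x, 0)
        + transpose_gradient(state.D_y - state.b_y, 1)
        + transpose_gradient(state.D_z - state.b_z, 2))
    rhs = rhs + cfg.beta * (state.D_w - state.b_w)
    denom = cfg.mu + cfg.alpha * laplacian_spectrum(arr.shape) + cfg.beta
    if np.any(denom <= 0):
        raise ValueError("singular f-subproblem: mu + beta must be positive")
    out = sfft.irfftn(sfft.rfftn(rhs) / denom, s=arr.shape)
    if isinstance(f_j, Volume3D):
        return Volume3D(out, f_j.voxel_size_mm, f_j.origin_mm.copy())
    return out


def update_bregman(state: BregmanState, f_new, cfg: DenoiseConfig,
                   bm3d_params: BM3DParams = BM3DParams(),
                   bm3d_of_f: np.ndarray | None = None) -> BregmanState:
    """Shrinkage and multiplier updates of all four channels.

    D_a = shrink(grad_a f + b_a, 1/alpha) for the gradient channels and
    D_w = shrink(BM3D(f) + b_w, 1/beta); the multipliers accumulate the
    residual constraint violations.  BM3D(f) is evaluated once and reused
    (or supplied via ``bm3d_of_f``).
    """
    arr = _as_array(f_new)
    gx, gy, gz = gradient_ops(arr)
    w = (np.asarray(bm3d_of_f, dtype=float) if bm3d_of_f is not None
         else _as_array(bm3d_denoise(arr, bm3d_params)))
    D_x = shrink(gx + state.b_x, 1.0 / cfg.alpha)
    D_y = shrink(gy + state.b_y, 1.0 / cfg.alpha)
    D_z = shrink(gz + state.b_z, 1.0 / cfg.alpha)
    D_w = shrink(w + state.b_w, 1.0 / cfg.beta)
    return BregmanState(
        D_x=D_x, D_y=D_y, D_z=D_z, D_w=D_w,
        b_x=state.b_x + gx - D_x,
        b_y=state.b_y + gy - D_y,
        b_z=state.b_z + gz - D_z,
        b_w=state.b_w + w - D_w,
        k=state.k + 1)


def denoise_objective(f_hat, f_j, cfg: DenoiseConfig,
                      bm3d_of_f: np.ndarray | None = None,
                      bm3d_params: BM3DParams = BM3DParams()) -> float:
    """Surrogate objective: TV + mu ||f - f_j||^2 + delta |BM3D(f)|_1."""
    a = _as_array(f_hat)
    b = _as_array(f_j)
    w = (np.asarray(bm3d_of_f, dtype=float) if bm3d_of_f is not None
         else _as_array(bm3d_denoise(a, bm3d_params)))
    return (total_variation(a) + cfg.mu * float(np.sum((a - b) ** 2))
            + cfg.delta * float(np.abs(w).sum()))


def tv_bm3d_denoise_step(f_j, cfg: DenoiseConfig = DenoiseConfig(),
                         bm3d_params: BM3DParams = BM3DParams(),
                         return_history: bool = False):
    """Run the full split-Bregman inner loop starting from f_j.

    State starts at zero and ``cfg.inner_loops`` iterations of
    (D/b update from the current volume, then FFT f-update) are applied;
    ``inner_loops=0`` returns the input unchanged.  With
    ``return_history`` the surrogate objective before each loop is also
    returned.
    """
    arr = _as_array(f_j)
    if not np.all(np.isfinite(arr)):
        raise ValueError("input volume must be finite")
    state = BregmanState.zeros(arr.shape)
    f_hat = arr.copy()
    history = []
    for _ in range(cfg.inner_loops):
        w = _as_array(bm3d_denoise(f_hat, bm3d_params))
        if return_history:
            history.append(denoise_objective(f_hat, arr, cfg, bm3d_of_f=w))
        state = update_bregman(state, f_hat, cfg, bm3d_params, bm3d_of_f=w)
        f_hat = _as_array(solve_f_subproblem(arr, state, cfg))
    if isinstance(f_j, Volume3D):
        out = Volume3D(f_hat, f_j.voxel_size_mm, f_j.origin_mm.copy())
    else:
        out = f_hat
    if return_history:
        return out, history
    return out
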