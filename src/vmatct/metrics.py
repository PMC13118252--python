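"""Image-quality metrics: contrast-to-noise ratio and structural similarity.

CNR compares a ~1 cm^3 box in an air cavity (or bone) against a ~1 cm^3
reference box in uniform soft tissue:

    CNR = (mean_VOI - mean_ref) / sd_ref        (population sd)

An air-cavity VOI gives a negative numerator in attenuation units, so the
success criterion (CNR strictly greater than 2) is applied to the
magnitude; the signed value is exposed separately.

SSIM is evaluated from local (per axial slice, Gaussian-windowed) means
and standard deviations of the test and reference volumes,

    SSIM = (2 m_i m_r + C1)(2 s_i s_r + C2)
           / ((m_i^2 + m_r^2 + C1)(s_i^2 + s_r^2 + C2))

and reported as the mean of the local map over the evaluation mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import Volume3D, VolumeMask

__all__ = ["EvaluationBoxes", "SsimParams", "cnr", "cnr_signed",
           "is_successful", "ssim", "SUCCESS_CNR_THRESHOLD"]

#: reconstructions with |CNR| strictly above this count as successful
SUCCESS_CNR_THRESHOLD = 2.0


@dataclass(frozen=True)
class EvaluationBoxes:
    """Axis-aligned index boxes (inclusive lo, exclusive hi, per axis)."""

    voi_lo: tuple[int, int, int]
    voi_hi: tuple[int, int, int]
    ref_lo: tuple[int, int, int]
    ref_hi: tuple[int, int, int]

    def __post_init__(self):
        for lo, hi in ((self.voi_lo, self.voi_hi), (self.ref_lo, self.ref_hi)):
            n = 1
            for a in range(3):
                if hi[a] <= lo[a] or lo[a] < 0:
                    raise ValueError("box bounds must satisfy 0 <= lo < hi")
                n *= hi[a] - lo[a]
            if n < 8:
                raise ValueError("each box must contain at least 8 voxels")
        if self._overlaps():
            raise ValueError("VOI and reference boxes must be disjoint")

    def _overlaps(self) -> bool:
        return all(self.voi_lo[a] < self.ref_hi[a] and
                   self.ref_lo[a] < self.voi_hi[a] for a in range(3))

    def voi_slices(self):
        return tuple(slice(l, h) for l, h in zip(self.voi_lo, self.voi_hi))

    def ref_slices(self):
        return tuple(slice(l, h) for l, h in zip(self.ref_lo, self.ref_hi))

    def check_inside(self, shape) -> None:
        for hi in (self.voi_hi, self.ref_hi):
            if any(hi[a] > shape[a] for a in range(3)):
                raise ValueError("evaluation box extends outside the volume")


def _values(volume) -> np.ndarray:
    return volume.values if isinstance(volume, Volume3D) else np.asarray(
        volume, dtype=float)


def cnr_signed(volume, boxes: EvaluationBoxes) -> float:
    """Signed CNR: (mean_VOI - mean_ref) / population sd_ref."""
    arr = _values(volume)
    boxes.check_inside(arr.shape)
    voi = arr[boxes.voi_slices()]
    ref = arr[boxes.ref_slices()]
    sd = float(ref.std())  # population sd
    if sd == 0.0:
        raise ValueError("reference box has zero standard deviation")
    return float((voi.mean() - ref.mean()) / sd)


def cnr(volume, boxes: EvaluationBoxes) -> float:
    """Magnitude of the contrast-to-noise ratio."""
    return abs(cnr_signed(volume, boxes))


def is_successful(cnr_value: float) -> bool:
    """True iff the (magnitude) CNR is strictly higher than the threshold."""
    if not np.isfinite(cnr_value):
        raise ValueError("CNR must be finite")
    return bool(cnr_value > SUCCESS_CNR_THRESHOLD)


@dataclass(frozen=True)
class SsimParams:
    """Window and regularization constants of the SSIM map.

    ``C1 = (0.01 L)^2`` and ``C2 = (0.03 L)^2`` by default, with L the
    dynamic range of the reference; the local statistics use a per-slice
    2D Gaussian window (sigma 1.5, 11 x 11 support).
    """

    window_sigma: float = 1.5
    window_size: int = 11
    dynamic_range: float | None = None
    C1: float | None = None
    C2: float | None = None

    def resolve(self, reference: np.ndarray):
        L = self.dynamic_range
        if L is None:
            L = float(reference.max() - reference.min())
            if L == 0.0:
                L = 1.0
        c1 = self.C1 if self.C1 is not None else (0.01 * L) ** 2
        c2 = self.C2 if self.C2 is not None else (0.03 * L) ** 2
        if c1 <= 0 or c2 <= 0:
            raise ValueError("C1 and C2 must be positive")
        return c1, c2


def _local_stats(arr: np.ndarray, params: SsimParams):
    """Per-axial-slice Gaussian-window local mean and sd."""
    truncate = ((params.window_size - 1) / 2.0) / params.window_sigma
    sig = (params.window_sigma, params.window_sigma, 0.0)
    mean = ndimage.gaussian_filter(arr, sigma=sig, truncate=truncate)
    sq = ndimage.gaussian_filter(arr * arr, sigma=sig, truncate=truncate)
    var = np.maximum(sq - mean * mean, 0.0)
    return mean, np.sqrt(var)


def ssim(test, reference, params: SsimParams = SsimParams(),
         mask: VolumeMask | None = None) -> float:
    """Masked mean of the local mean/variance similarity map."""
    a = _values(test)
    b = _values(reference)
    if a.shape != b.shape:
        raise ValueError("test and reference volumes must share a shape")
    c1, c2 = params.resolve(b)
    mu_a, sd_a = _local_stats(a, params)
    mu_b, sd_b = _local_stats(b, params)
    num = (2.0 * mu_a * mu_b + c1) * (2.0 * sd_a * sd_b + c2)
    den = (mu_a ** 2 + mu_b ** 2 + c1) * (sd_a ** 2 + sd_b ** 2 + c2)
    smap = num / den
    if mask is not None:
        if mask.mask.shape != a.shape:
            raise ValueError("mask shape mismatch")
        return float(smap[mask.mask].mean())
    return float(smap.mean())
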