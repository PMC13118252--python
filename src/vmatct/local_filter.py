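"""Local (lambda-tomography) filtering of detector images.

Truncated portal images only carry reliable information locally, so the
data-fidelity term compares *locally filtered* measured and simulated
projections, ``(R f)_L`` vs ``p_L``, instead of the raw line integrals.
The filter L is a compact 1D convolution ``e_R`` applied along the
transverse detector axis u, row by row:

    p_L(u, v) = p(u, v) * e_R(u)

The default kernel is the negated discrete second derivative
``[-1, 2, -1]`` -- the canonical local lambda filter, which annihilates
constants and linear ramps and so suppresses the unknown smooth offset
introduced by truncation.  Alternative taps (or the identity kernel) can be
supplied through the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import DetectorMaskSet, ProjectionSet

__all__ = [
    "LocalFilterKernel",
    "local_filter_image",
    "local_filter_set",
    "erode_detector_masks",
]


@dataclass(frozen=True)
class LocalFilterKernel:
    """Compact 1D convolution kernel along the detector u axis.

    The default lambda kernel has zero tap sum (annihilates constants);
    the identity kernel, used to disable local filtering, does not.
    """

    taps: tuple[float, ...] = (-1.0, 2.0, -1.0)
    normalization: float = 1.0

    def __post_init__(self):
        taps = tuple(float(t) for t in self.taps)
        object.__setattr__(self, "taps", taps)
        if len(taps) == 0 or len(taps) % 2 == 0:
            raise ValueError("kernel must have an odd, positive number of taps")
        if not np.all(np.isfinite(taps)) or not np.isfinite(self.normalization):
            raise ValueError("kernel taps and normalization must be finite")

    @classmethod
    def lambda_default(cls) -> "LocalFilterKernel":
        """Negated second difference: the default local lambda filter."""
        return cls((-1.0, 2.0, -1.0))

    @classmethod
    def identity(cls) -> "LocalFilterKernel":
        """Single-tap identity kernel (local filtering disabled)."""
        return cls((1.0,))

    @property
    def half_width(self) -> int:
        return (len(self.taps) - 1) // 2

    def as_array(self) -> np.ndarray:
        return np.asarray(self.taps, dtype=float) * self.normalization


def local_filter_image(image: np.ndarray,
                       kernel: LocalFilterKernel) -> np.ndarray:
    """Convolve each detector row (fixed v) with the kernel along u.

    Boundaries use symmetric reflection so no gradient is fabricated at the
    detector edge; output shape equals input shape.
    """
    image = np.asarray(image, dtype=float)
    if len(kernel.taps) > image.shape[0]:
        raise ValueError("kernel is longer than the detector u extent")
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    return ndimage.convolve1d(image, kernel.as_array(), axis=0, mode="reflect")


def local_filter_set(projections: ProjectionSet,
                     kernel: LocalFilterKernel) -> ProjectionSet:
    """Apply the same local filter to every view; angles/masks pass through."""
    filtered = np.stack([local_filter_image(img, kernel)
                         for img in projections.images])
    return ProjectionSet(filtered, projections.gantry_angles_deg.copy(),
                         projections.masks)


def erode_detector_masks(masks: DetectorMaskSet,
                         kernel: LocalFilterKernel) -> DetectorMaskSet:
    """Erode each mask along u by the kernel half-width.

    Pixels whose filtered value mixes in-aperture and out-of-aperture
    signal are excluded from the masked fidelity update.
    """
    hw = kernel.half_width
    if hw == 0:
        return DetectorMaskSet(masks.masks.copy())
    structure = np.ones((2 * hw + 1, 1), dtype=bool)
    eroded = np.stack([
        ndimage.binary_erosion(m, structure=structure, border_value=1)
        for m in masks.masks
    ])
    return DetectorMaskSet(eroded)
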