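"""RGB channel decomposition and Bragg-pixel classification.

A camera pixel dominated by first-order grating diffraction is strongly
green under the acquisition geometry modeled here, while broadband scatter
is color-neutral.  Dividing the green channel by the red channel therefore
yields a ratio image in which Bragg pixels stand out (ratio >> 1) and
scatter sits near 1; thresholding that ratio produces the Bragg pixel mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .simulate import RED, GREEN, BLUE

__all__ = [
    "DEFAULT_EPSILON",
    "RatioImage",
    "PixelMask",
    "split_channels",
    "ratio_image",
    "threshold_bragg",
    "suggest_threshold",
]

#: One 16-bit intensity quantum; default stabilizer for channel division.
DEFAULT_EPSILON = 1.0 / 65535.0


@dataclass
class RatioImage:
    """Per-pixel green:red ratio plus the epsilon used to stabilize it."""

    values: np.ndarray
    epsilon: float


@dataclass
class PixelMask:
    """Boolean pixel selection with a record of which stage produced it."""

    mask: np.ndarray
    provenance: str = "manual"

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())


def split_channels(frame: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB frame into (red, green, blue) single-channel images."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError(f"expected an RGB frame of shape (rows, cols, 3), got {frame.shape}")
    return frame[..., RED], frame[..., GREEN], frame[..., BLUE]


def ratio_image(green: np.ndarray, red: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> RatioImage:
    """Elementwise green / (red + epsilon).

    ``epsilon`` guards against division blow-up on dark pixels; with
    ``epsilon = 0`` every red pixel must be strictly positive.
    """
    green = np.asarray(green, dtype=float)
    red = np.asarray(red, dtype=float)
    if green.shape != red.shape:
        raise ValueError("green and red channels must have the same shape")
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if epsilon == 0 and np.any(red <= 0):
        raise ValueError("red channel contains non-positive pixels; set epsilon > 0")
    return RatioImage(values=green / (red + epsilon), epsilon=float(epsilon))


def threshold_bragg(ratio: RatioImage, tau: float) -> PixelMask:
    """Pixels whose green:red ratio is at least ``tau`` (inclusive)."""
    if not tau > 0:
        raise ValueError("tau must be > 0")
    return PixelMask(mask=ratio.values >= tau, provenance="threshold")


def suggest_threshold(ratio: RatioImage, clip_quantile: float = 0.95) -> float:
    """Data-driven ratio threshold: Otsu's two-class split of the histogram.

    The ratio distribution has a long right tail where the red channel is
    nearly dark, so values are clipped at ``clip_quantile`` before building
    the histogram — the ceiling then sits near the Bragg mode instead of at
    an outlier, and tail pixels simply count toward the high class.  The
    returned threshold is on the original ratio scale.
    """
    values = np.asarray(ratio.values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("ratio image is empty")
    hi = float(np.quantile(values, clip_quantile))
    clipped = np.minimum(values, hi)
    if clipped.max() == clipped.min():
        raise ValueError("ratio image is (effectively) constant; choose tau manually")
    return float(threshold_otsu(clipped, nbins=512))
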