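"""Refinement of the Bragg mask to pixels consistent with the height law.

Fluorescence intensity of the dye-doped lipid is proportional to the local
multilayer height, so it serves as a per-pixel height proxy.  Within each
fluorescence (height) bin, pixels whose initial diffraction intensity lies
within ``k_sd`` sample standard deviations of the bin mean are kept; pixels
that diffract anomalously for their height — scatter contamination, print
defects — are rejected.  This is the pixel-selection step that buys the
sensorgram its signal-to-noise ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .channels import PixelMask

__all__ = [
    "BinnedStats",
    "HeightDiffractionFit",
    "bin_by_fluorescence",
    "sd_band_select",
    "fit_height_diffraction",
]


@dataclass
class BinnedStats:
    """Per-fluorescence-bin statistics of the initial green intensity.

    ``counts`` covers every bin (including ones later dropped for low
    occupancy) and sums to the number of masked pixels.  ``sd`` is the
    sample (n-1) standard deviation; NaN where a bin has fewer than two
    pixels.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    mean_green: np.ndarray
    sd_green: np.ndarray

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class HeightDiffractionFit:
    """OLS fit of initial green diffraction on fluorescence (height proxy)."""

    slope: float
    intercept: float
    r_squared: float
    n_pixels: int


def _mask_array(mask) -> np.ndarray:
    m = mask.mask if isinstance(mask, PixelMask) else np.asarray(mask)
    if m.dtype != bool:
        raise ValueError("mask must be boolean")
    return m


def bin_by_fluorescence(fluor: np.ndarray, mask, n_bins: int) -> tuple[np.ndarray, np.ndarray]:
    """Assign each masked pixel to one of ``n_bins`` equal-width fluorescence bins.

    Bins span [min, max] of the masked fluorescence values; the last bin is
    right-inclusive.  Returns ``(bin_index, edges)`` where ``bin_index`` is
    an image of bin numbers with -1 outside the mask, and ``edges`` has
    length ``n_bins + 1``.  Constant fluorescence collapses to a single bin.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    m = _mask_array(mask)
    fluor = np.asarray(fluor, dtype=float)
    if fluor.shape != m.shape:
        raise ValueError("fluorescence image and mask shapes differ")
    values = fluor[m]
    if values.size == 0:
        raise ValueError("mask selects no pixels")
    lo, hi = float(values.min()), float(values.max())
    bin_index = np.full(m.shape, -1, dtype=int)
    if lo == hi or n_bins == 1:
        edges = np.array([lo, hi])
        bin_index[m] = 0
        return bin_index, edges
    edges = np.linspace(lo, hi, n_bins + 1)
    # interior edges only: values below edges[1] -> 0, ..., max value -> n_bins-1
    bin_index[m] = np.digitize(values, edges[1:-1])
    return bin_index, edges


def sd_band_select(green0: np.ndarray, fluor: np.ndarray, mask, n_bins: int = 10,
                   k_sd: float = 1.0, min_bin_count: int = 3,
                   method: str = "bin") -> tuple[PixelMask, BinnedStats]:
    """Keep pixels whose initial green intensity is typical for their height.

    ``green0`` is the pre-addition (baseline) green channel.  With the
    default ``method="bin"``, each fluorescence bin keeps pixels with
    ``|green0 - bin mean| <= k_sd * bin SD`` (sample SD, inclusive
    boundary); bins with fewer than ``min_bin_count`` pixels are dropped
    entirely.  ``method="residual"`` instead bands on the residuals of a
    global OLS fit of green0 on fluorescence.  The returned mask is always
    a subset of the input mask.
    """
    m = _mask_array(mask)
    green0 = np.asarray(green0, dtype=float)
    if green0.shape != m.shape:
        raise ValueError("green0 image and mask shapes differ")
    if method not in ("bin", "residual"):
        raise ValueError("method must be 'bin' or 'residual'")

    bin_index, edges = bin_by_fluorescence(fluor, m, n_bins)
    n_actual = max(1, len(edges) - 1)
    counts = np.zeros(n_actual, dtype=int)
    means = np.full(n_actual, np.nan)
    sds = np.full(n_actual, np.nan)
    keep = np.zeros(m.shape, dtype=bool)

    if method == "residual":
        fit = fit_height_diffraction(green0, fluor, m)
        resid = green0 - (fit.slope * np.asarray(fluor, dtype=float) + fit.intercept)
        band = k_sd * resid[m].std(ddof=1)
        keep = m & (np.abs(resid) <= band)

    for b in range(n_actual):
        sel = bin_index == b
        n = int(sel.sum())
        counts[b] = n
        if n >= 2:
            means[b] = green0[sel].mean()
            sds[b] = green0[sel].std(ddof=1)
        elif n == 1:
            means[b] = green0[sel].mean()
        if method == "bin":
            if n < min_bin_count:
                continue
            keep |= sel & (np.abs(green0 - means[b]) <= k_sd * sds[b])

    if not keep.any():
        raise ValueError(
            "no pixels survive SD-band selection (all bins below the minimum "
            f"occupancy of {min_bin_count}); use fewer bins"
        )
    return PixelMask(mask=keep, provenance="sd_band"), BinnedStats(
        bin_edges=edges, counts=counts, mean_green=means, sd_green=sds
    )


def fit_height_diffraction(green0: np.ndarray, fluor: np.ndarray, mask) -> HeightDiffractionFit:
    """Ordinary least squares of initial green intensity on fluorescence.

    Below the diffraction saturation height both signals are affine in the
    grating height, so on ideal pixels the fit is a straight line whose
    slope is the ratio of the diffraction and fluorescence coefficients.
    """
    m = _mask_array(mask)
    x = np.asarray(fluor, dtype=float)[m]
    y = np.asarray(green0, dtype=float)[m]
    if x.size < 2:
        raise ValueError("need at least 2 masked pixels to fit")
    if np.all(x == x[0]):
        raise ValueError("fluorescence is constant over the mask; no height contrast to fit")
    res = stats.linregress(x, y)
    return HeightDiffractionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue) ** 2,
        n_pixels=int(x.size),
    )
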