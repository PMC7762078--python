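"""Time-resolved diffraction signals from selected pixels.

A sensorgram is the mean green diffraction intensity over a pixel mask,
frame by frame, normalized against its pre-addition baseline.  Percent
change at a query time, final/initial change-ratio images, height-binned
responses and test-minus-control differentials are derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import DEFAULT_EPSILON, PixelMask
from .select import bin_by_fluorescence
from .simulate import GREEN, ImageStack

__all__ = [
    "Sensorgram",
    "BinnedResponse",
    "extract_sensorgram",
    "percent_change",
    "change_ratio_image",
    "height_binned_response",
    "compare_to_control",
]


@dataclass
class Sensorgram:
    """Mean masked green intensity per frame, with its baseline value."""

    t_min: np.ndarray
    intensity: np.ndarray
    baseline: float
    label: str = "sample"

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if len(self.t_min) != len(self.intensity):
            raise ValueError("t_min and intensity must have equal length")
        if len(self.t_min) > 1 and not np.all(np.diff(self.t_min) > 0):
            raise ValueError("t_min must be strictly increasing")
        if not self.baseline > 0:
            raise ValueError("baseline intensity must be > 0")

    def percent_change(self, t_query_min: float) -> float:
        return percent_change(self, t_query_min)

    def relative(self) -> np.ndarray:
        """Baseline-normalized trace I(t) / I0."""
        return self.intensity / self.baseline


@dataclass
class BinnedResponse:
    """Percent change at a query time, per fluorescence (height) bin."""

    bin_centers: np.ndarray
    percent_change: np.ndarray
    counts: np.ndarray


def _baseline_indices(n_frames: int, baseline_window) -> np.ndarray:
    if isinstance(baseline_window, slice):
        idx = np.arange(n_frames)[baseline_window]
    else:
        idx = np.asarray(baseline_window, dtype=int)
    if idx.size == 0:
        raise ValueError("baseline window is empty")
    if idx.min() < 0 or idx.max() >= n_frames:
        raise ValueError("baseline window indices out of range")
    return idx


def extract_sensorgram(stack: ImageStack, mask, baseline_window,
                       label: str = "sample") -> Sensorgram:
    """Mean green intensity over ``mask`` per frame, with baseline.

    ``baseline_window`` is a slice or index array of pre-addition frames;
    the baseline is the mean of the trace over that window.
    """
    m = mask.mask if isinstance(mask, PixelMask) else np.asarray(mask)
    if m.dtype != bool:
        raise ValueError("mask must be boolean")
    if m.shape != stack.image_shape:
        raise ValueError("mask shape does not match the stack")
    if not m.any():
        raise ValueError("mask selects no pixels")
    trace = stack.frames[:, :, :, GREEN][:, m].mean(axis=1)
    idx = _baseline_indices(stack.n_frames, baseline_window)
    baseline = float(trace[idx].mean())
    return Sensorgram(t_min=stack.times_min, intensity=trace, baseline=baseline, label=label)


def percent_change(s: Sensorgram, t_query_min: float) -> float:
    """Percent change of intensity vs baseline at the recorded frame nearest
    ``t_query_min`` (ties resolve to the earlier frame)."""
    if not (s.t_min[0] <= t_query_min <= s.t_min[-1]):
        raise ValueError(
            f"t_query {t_query_min} min outside recorded range [{s.t_min[0]}, {s.t_min[-1]}]"
        )
    idx = int(np.argmin(np.abs(s.t_min - t_query_min)))  # argmin takes the first (earlier) tie
    return 100.0 * (s.intensity[idx] - s.baseline) / s.baseline


def change_ratio_image(stack: ImageStack, frame_final: int, frame_initial: int,
                       epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Per-pixel green(final) / (green(initial) + epsilon); 1 means no change."""
    n = stack.n_frames
    for name, f in (("frame_final", frame_final), ("frame_initial", frame_initial)):
        if not -n <= f < n:
            raise ValueError(f"{name}={f} out of range for a {n}-frame stack")
    g_final = stack.frames[frame_final, :, :, GREEN]
    g_initial = stack.frames[frame_initial, :, :, GREEN]
    return g_final / (g_initial + epsilon)


def height_binned_response(stack: ImageStack, fluor: np.ndarray, mask, n_bins: int,
                           t_query_min: float, baseline_window,
                           min_bin_count: int = 3) -> BinnedResponse:
    """Percent change at ``t_query_min`` per fluorescence (height) bin.

    Bins with fewer than ``min_bin_count`` pixels are omitted.
    """
    bin_index, edges = bin_by_fluorescence(fluor, mask, n_bins)
    centers = 0.5 * (edges[:-1] + edges[1:]) if len(edges) > 2 else np.array([edges.mean()])
    out_centers, out_pct, out_counts = [], [], []
    for b in range(max(1, len(edges) - 1)):
        sel = bin_index == b
        n = int(sel.sum())
        if n < min_bin_count:
            continue
        s = extract_sensorgram(stack, sel, baseline_window, label=f"bin{b}")
        out_centers.append(centers[b])
        out_pct.append(percent_change(s, t_query_min))
        out_counts.append(n)
    if not out_centers:
        raise ValueError("no fluorescence bin reaches the minimum occupancy")
    return BinnedResponse(
        bin_centers=np.asarray(out_centers),
        percent_change=np.asarray(out_pct),
        counts=np.asarray(out_counts, dtype=int),
    )


def compare_to_control(s_test: Sensorgram, s_control: Sensorgram, t_query_min: float) -> float:
    """Differential percent change, test minus control, at ``t_query_min``."""
    lo = max(s_test.t_min[0], s_control.t_min[0])
    hi = min(s_test.t_min[-1], s_control.t_min[-1])
    if lo > hi:
        raise ValueError("sensorgram time ranges do not overlap")
    if not lo <= t_query_min <= hi:
        raise ValueError(f"t_query {t_query_min} min outside the overlapping range [{lo}, {hi}]")
    return percent_change(s_test, t_query_min) - percent_change(s_control, t_query_min)
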