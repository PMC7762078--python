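"""Forward model for lipid multilayer grating diffraction movies.

Lipid multilayer gratings are arrays of sub-100 nm tall fluid lipid lines
that diffract white light; analyte binding reshapes the lines and changes
the diffracted (green, under the acquisition geometry modeled here)
intensity.  This module renders ground-truthed synthetic data embodying the
transduction physics the analysis pipeline assumes:

* per-pixel grating height ``h`` (nm) drawn lognormally per printed spot
  (heterogeneous ink transfer);
* dye fluorescence proportional to ``h`` (fluorescence is the height proxy);
* first-order (Bragg) diffraction linear in ``h`` up to one tenth of the
  grating line width, then saturated;
* Bragg pixels green-dominant, broadband scatter pixels color-neutral;
* a pseudo-first-order binding response that multiplies the diffracted
  intensity after analyte addition, optionally scaled by relative height;
* a minority population of "defect" grating pixels whose diffraction does
  not follow the height law and flickers frame to frame — the pixels the
  SD-band selection stage exists to reject;
* additive Gaussian camera noise, clipped at zero.

All intensities are dimensionless arbitrary units in [0, 1]; quantization
to 16 bits happens only at file-write time (see :mod:`braggsense.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import max_grating_height

__all__ = [
    "ConfigError",
    "OpticsParams",
    "BindingParams",
    "SpotSpec",
    "SimulationConfig",
    "HeightMap",
    "GroundTruth",
    "ImageStack",
    "diffraction_efficiency",
    "binding_response",
    "build_height_map",
    "render_fluorescence",
    "render_diffraction_frame",
    "simulate_timelapse",
]

# RGB channel order used throughout the package.
RED, GREEN, BLUE = 0, 1, 2


class ConfigError(ValueError):
    """Raised when a simulation or analysis configuration is invalid."""


@dataclass(frozen=True)
class OpticsParams:
    """Optical coefficients of the forward model.

    Parameters
    ----------
    fluorescence_per_nm:
        Fluorescence signal per nm of multilayer height (a.u./nm).
    diffraction_per_nm:
        Green diffracted signal per nm of height below saturation (a.u./nm).
    bragg_green_red_contrast:
        Factor by which a Bragg pixel's diffracted green exceeds the red
        (and blue) leakage into the other channels; must exceed 1 for the
        green:red ratio to separate Bragg pixels from scatter.
    background_level:
        Dark/stray-light offset added to every channel (a.u.).
    scatter_level_range:
        Interval (a.u.) from which the brightness of broadband,
        color-neutral scatter pixels is drawn.
    """

    fluorescence_per_nm: float = 0.012
    diffraction_per_nm: float = 0.02
    bragg_green_red_contrast: float = 4.0
    background_level: float = 0.01
    scatter_level_range: tuple[float, float] = (0.2, 0.6)


@dataclass(frozen=True)
class BindingParams:
    """Pseudo-first-order analyte binding response of one spot.

    ``amplitude`` is the steady-state fractional increase of green
    diffraction for a full-height grating; ``rate_per_min`` is the observed
    approach rate (for analyte concentrations far above the dissociation
    constant, k_obs ~ k_on * C).  With ``height_scaling`` the effective
    amplitude is ``amplitude * min(h / h_max, 1)`` so taller gratings
    respond more strongly.
    """

    amplitude: float = 0.0
    rate_per_min: float = 0.6
    height_scaling: bool = True


@dataclass(frozen=True)
class SpotSpec:
    """One printed grating spot.

    ``region`` is a half-open pixel rectangle (row0, col0, row1, col1).
    Heights are lognormal with the given median (nm) and log-sigma;
    ``sigma_log = 0`` gives a uniform-height spot.  ``defect_fraction`` of
    the spot's pixels are rendered as anomalous gratings: green-dominant
    (so they pass the Bragg ratio threshold) but with a diffraction level
    drawn from ``defect_level_range`` independent of height, an extra
    per-frame flicker of SD ``defect_noise_sd``, and no analyte response.
    """

    name: str
    region: tuple[int, int, int, int]
    median_height_nm: float
    sigma_log: float = 0.15
    functionalized: bool = False
    response: BindingParams = field(default_factory=BindingParams)
    defect_fraction: float = 0.0
    defect_noise_sd: float = 0.0
    defect_level_range: tuple[float, float] = (0.1, 0.9)


@dataclass
class SimulationConfig:
    """Full parameter set for one synthetic acquisition."""

    image_shape: tuple[int, int] = (128, 128)
    line_width_nm: float = 300.0
    frame_rate_per_min: float = 5.0
    duration_min: float = 20.0
    analyte_time_min: float = 5.0
    spots: list[SpotSpec] = field(default_factory=list)
    optics: OpticsParams = field(default_factory=OpticsParams)
    noise_sd: float = 0.005
    scatter_fraction: float = 0.08
    seed: int = 0

    @property
    def max_height_nm(self) -> float:
        """Saturation height of the diffraction law (line width / 10)."""
        return max_grating_height(self.line_width_nm)

    @property
    def n_frames(self) -> int:
        return int(math.floor(self.duration_min * self.frame_rate_per_min)) + 1

    def frame_times(self) -> np.ndarray:
        """Acquisition timestamps in minutes from the start."""
        return np.arange(self.n_frames) / self.frame_rate_per_min

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every offending field."""
        problems: list[str] = []
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            problems.append("image_shape must be positive")
        if not self.line_width_nm > 0:
            problems.append("line_width_nm must be > 0")
        if not self.frame_rate_per_min > 0:
            problems.append("frame_rate_per_min must be > 0")
        if not self.duration_min > 0:
            problems.append("duration_min must be > 0")
        if not 0 < self.analyte_time_min < self.duration_min:
            problems.append("analyte_time_min must lie strictly inside (0, duration_min)")
        if self.noise_sd < 0:
            problems.append("noise_sd must be >= 0")
        if not 0 <= self.scatter_fraction <= 1:
            problems.append("scatter_fraction must be in [0, 1]")
        if self.optics.bragg_green_red_contrast <= 1:
            problems.append("optics.bragg_green_red_contrast must be > 1")
        for name in ("fluorescence_per_nm", "diffraction_per_nm", "background_level"):
            if getattr(self.optics, name) < 0:
                problems.append(f"optics.{name} must be >= 0")
        for i, spot in enumerate(self.spots):
            r0, c0, r1, c1 = spot.region
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                problems.append(f"spots[{i}].region outside image or empty")
            if not spot.median_height_nm > 0:
                problems.append(f"spots[{i}].median_height_nm must be > 0")
            if spot.sigma_log < 0:
                problems.append(f"spots[{i}].sigma_log must be >= 0")
            if spot.response.amplitude < 0:
                problems.append(f"spots[{i}].response.amplitude must be >= 0")
            if not spot.response.rate_per_min > 0:
                problems.append(f"spots[{i}].response.rate_per_min must be > 0")
            if not spot.functionalized and spot.response.amplitude != 0:
                problems.append(f"spots[{i}] is a control (not functionalized) but has nonzero amplitude")
            if not 0 <= spot.defect_fraction <= 1:
                problems.append(f"spots[{i}].defect_fraction must be in [0, 1]")
            if spot.defect_noise_sd < 0:
                problems.append(f"spots[{i}].defect_noise_sd must be >= 0")
        for i in range(len(self.spots)):
            for j in range(i + 1, len(self.spots)):
                if _rects_overlap(self.spots[i].region, self.spots[j].region):
                    problems.append(f"spots[{i}] and spots[{j}] overlap")
        if problems:
            raise ConfigError("invalid simulation config: " + "; ".join(problems))


def _rects_overlap(a: tuple[int, int, int, int], b: tuple[int, int, int, int]) -> bool:
    ar0, ac0, ar1, ac1 = a
    br0, bc0, br1, bc1 = b
    return ar0 < br1 and br0 < ar1 and ac0 < bc1 and bc0 < ac1


@dataclass
class HeightMap:
    """Per-pixel grating geometry: height (nm), spot label, Bragg flag.

    ``spot_label`` is the spot index, -1 on background.  ``bragg_truth`` is
    True exactly where ``h > 0`` (grating pixels).
    """

    h: np.ndarray
    spot_label: np.ndarray
    bragg_truth: np.ndarray


@dataclass
class GroundTruth:
    """Everything a test oracle needs about a simulated scene."""

    height_map: HeightMap
    injected_amplitudes: dict[str, float]
    scatter_mask: np.ndarray
    defect_mask: np.ndarray


@dataclass
class ImageStack:
    """Time-ordered RGB frames with acquisition timestamps (minutes)."""

    frames: np.ndarray  # (T, rows, cols, 3) float
    times_min: np.ndarray  # (T,)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times_min = np.asarray(self.times_min, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (T, rows, cols, 3)")
        if len(self.times_min) != self.frames.shape[0]:
            raise ValueError("times_min length must match number of frames")
        if len(self.times_min) > 1 and not np.all(np.diff(self.times_min) > 0):
            raise ValueError("times_min must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    def green(self) -> np.ndarray:
        """The green channel of every frame, shape (T, rows, cols)."""
        return self.frames[..., GREEN]


def _check_finite_nonneg(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    if np.any(arr < 0):
        raise ValueError(f"{name} must be >= 0")
    return arr


def diffraction_efficiency(height_nm, line_width_nm: float, diffraction_per_nm: float):
    """Green diffracted intensity of a grating pixel (a.u.).

    Linear in height up to the saturation height ``line_width_nm / 10``,
    constant above it::

        D(h) = diffraction_per_nm * min(h, line_width_nm / 10)

    Accepts scalars or arrays of heights.
    """
    h = _check_finite_nonneg(height_nm, "height_nm")
    if not (np.isfinite(line_width_nm) and line_width_nm > 0):
        raise ValueError("line_width_nm must be finite and > 0")
    _check_finite_nonneg(diffraction_per_nm, "diffraction_per_nm")
    out = diffraction_per_nm * np.minimum(h, max_grating_height(line_width_nm))
    return float(out) if out.ndim == 0 else out


def binding_response(t_min, analyte_time_min: float, params: BindingParams,
                     height_nm=None, max_height_nm: float | None = None):
    """Fractional increase of green diffraction at time ``t_min``.

    Zero before analyte addition; afterwards a pseudo-first-order approach
    ``A_eff * (1 - exp(-k (t - t0)))`` to the steady-state amplitude.  With
    ``params.height_scaling`` the amplitude is scaled by ``min(h/h_max, 1)``
    and per-pixel heights must be supplied.  Broadcasts over ``t_min`` and
    ``height_nm``.
    """
    t = np.asarray(t_min, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_min must be >= 0")
    amp = np.asarray(params.amplitude, dtype=float)
    if params.height_scaling:
        if height_nm is None or max_height_nm is None:
            raise ValueError("height_scaling requires height_nm and max_height_nm")
        h = np.asarray(height_nm, dtype=float)
        amp = amp * np.minimum(h / max_height_nm, 1.0)
    dt = np.maximum(t - analyte_time_min, 0.0)
    out = amp * -np.expm1(-params.rate_per_min * dt)
    return float(out) if np.ndim(out) == 0 else out


def build_height_map(config: SimulationConfig, rng: np.random.Generator) -> HeightMap:
    """Draw per-pixel grating heights for every spot in the config."""
    shape = tuple(config.image_shape)
    h = np.zeros(shape)
    label = np.full(shape, -1, dtype=int)
    for i, spot in enumerate(config.spots):
        r0, c0, r1, c1 = spot.region
        block = (r1 - r0, c1 - c0)
        if spot.sigma_log == 0:
            heights = np.full(block, float(spot.median_height_nm))
        else:
            heights = rng.lognormal(math.log(spot.median_height_nm), spot.sigma_log, size=block)
        h[r0:r1, c0:c1] = heights
        label[r0:r1, c0:c1] = i
    return HeightMap(h=h, spot_label=label, bragg_truth=h > 0)


def render_fluorescence(height_map: HeightMap, optics: OpticsParams,
                        noise_sd: float = 0.0, rng: np.random.Generator | None = None) -> np.ndarray:
    """Render the dye fluorescence image (the height proxy channel).

    Pixel value = ``fluorescence_per_nm * h + background_level`` plus
    additive Gaussian noise, clipped at zero.
    """
    img = optics.fluorescence_per_nm * height_map.h + optics.background_level
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_diffraction_frame(height_map: HeightMap, config: SimulationConfig, t_min: float,
                             rng: np.random.Generator | None = None, *,
                             scatter_mask: np.ndarray | None = None,
                             scatter_levels: np.ndarray | None = None,
                             defect_mask: np.ndarray | None = None,
                             defect_levels: np.ndarray | None = None) -> np.ndarray:
    """Render one RGB frame at time ``t_min`` (minutes).

    Bragg pixels receive ``D(h) * (1 + response(t))`` in green and a
    ``1 / bragg_green_red_contrast`` leakage in red and blue, on top of the
    common background level.  Defect pixels (if given) receive their static
    anomalous level plus per-frame flicker instead of the height-law signal.
    Scatter pixels are overwritten with a color-neutral level.  Camera noise
    is added per channel; everything is clipped at zero.
    """
    opt = config.optics
    shape = tuple(config.image_shape)
    green = np.full(shape, opt.background_level)
    red = np.full(shape, opt.background_level)
    blue = np.full(shape, opt.background_level)
    h_max = config.max_height_nm

    for i, spot in enumerate(config.spots):
        in_spot = height_map.spot_label == i
        sel = in_spot & height_map.bragg_truth
        if defect_mask is not None:
            sel = sel & ~defect_mask
        if sel.any():
            d = diffraction_efficiency(height_map.h[sel], config.line_width_nm, opt.diffraction_per_nm)
            resp = binding_response(t_min, config.analyte_time_min, spot.response,
                                    height_map.h[sel], h_max)
            signal = d * (1.0 + resp)
            leak = signal / opt.bragg_green_red_contrast
            green[sel] += signal
            red[sel] += leak
            blue[sel] += leak
        if defect_mask is not None:
            dsel = in_spot & defect_mask
            if dsel.any():
                level = defect_levels[dsel]
                if spot.defect_noise_sd > 0 and rng is not None:
                    level = level + rng.normal(0.0, spot.defect_noise_sd, size=level.shape)
                level = np.clip(level, 0.0, None)
                green[dsel] += level
                red[dsel] += level / opt.bragg_green_red_contrast
                blue[dsel] += level / opt.bragg_green_red_contrast

    if scatter_mask is not None and scatter_mask.any():
        green[scatter_mask] = scatter_levels
        red[scatter_mask] = scatter_levels
        blue[scatter_mask] = scatter_levels

    frame = np.stack([red, green, blue], axis=-1)
    if config.noise_sd > 0:
        if rng is None:
            raise ValueError("noise_sd > 0 requires an rng")
        frame = frame + rng.normal(0.0, config.noise_sd, size=frame.shape)
    return np.clip(frame, 0.0, None)


def _place_scatter(config: SimulationConfig, height_map: HeightMap,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    shape = tuple(config.image_shape)
    scatter_mask = np.zeros(shape, dtype=bool)
    background = np.flatnonzero(~height_map.bragg_truth.ravel())
    n_scatter = int(round(config.scatter_fraction * background.size))
    levels = np.zeros(shape)
    if n_scatter > 0:
        chosen = rng.choice(background, size=n_scatter, replace=False)
        scatter_mask.ravel()[chosen] = True
        lo, hi = config.optics.scatter_level_range
        levels.ravel()[chosen] = rng.uniform(lo, hi, size=n_scatter)
    return scatter_mask, levels


def _place_defects(config: SimulationConfig, height_map: HeightMap,
                   rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    shape = tuple(config.image_shape)
    defect_mask = np.zeros(shape, dtype=bool)
    levels = np.zeros(shape)
    for i, spot in enumerate(config.spots):
        if spot.defect_fraction <= 0:
            continue
        members = np.flatnonzero((height_map.spot_label == i).ravel())
        n_defect = int(round(spot.defect_fraction * members.size))
        if n_defect == 0:
            continue
        chosen = rng.choice(members, size=n_defect, replace=False)
        defect_mask.ravel()[chosen] = True
        lo, hi = spot.defect_level_range
        levels.ravel()[chosen] = rng.uniform(lo, hi, size=n_defect)
    return defect_mask, levels


def simulate_timelapse(config: SimulationConfig) -> tuple[ImageStack, np.ndarray, GroundTruth]:
    """Run the full forward model.

    Returns the diffraction time lapse, the co-registered fluorescence
    image, and the ground truth (height map, injected response amplitudes,
    scatter and defect masks).  Identical config (including seed) gives
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    height_map = build_height_map(config, rng)
    scatter_mask, scatter_levels = _place_scatter(config, height_map, rng)
    defect_mask, defect_levels = _place_defects(config, height_map, rng)
    fluor = render_fluorescence(height_map, config.optics, config.noise_sd, rng)
    times = config.frame_times()
    frames = np.empty((len(times),) + tuple(config.image_shape) + (3,))
    for f, t in enumerate(times):
        frames[f] = render_diffraction_frame(
            height_map, config, t, rng,
            scatter_mask=scatter_mask, scatter_levels=scatter_levels[scatter_mask],
            defect_mask=defect_mask, defect_levels=defect_levels,
        )
    stack = ImageStack(frames=frames, times_min=times)
    truth = GroundTruth(
        height_map=height_map,
        injected_amplitudes={s.name: s.response.amplitude for s in config.spots},
        scatter_mask=scatter_mask,
        defect_mask=defect_mask,
    )
    return stack, fluor, truth
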