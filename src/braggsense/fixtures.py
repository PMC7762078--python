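"""Packaged simulation fixtures.

Two ready-made scenes ship with the package:

* ``thrombin_timelapse_config`` — aptamer + control gratings printed near
  the maximum useful height, 5 frames/min for 20 min, analyte at 5 min,
  injected steady-state response 20%; the end-to-end detection scenario.
* ``height_series_config`` — one heterogeneous grating with sub-saturation
  heights (median 12 nm), for the height-diffraction relation and
  height-binned response.
"""

from __future__ import annotations

from importlib import resources

import yaml

from .io import simulation_config_from_dict
from .simulate import SimulationConfig, SpotSpec

__all__ = ["thrombin_timelapse_config", "height_series_config", "rois_from_config"]


def _load(name: str, seed: int | None) -> SimulationConfig:
    text = resources.files("braggsense.configs").joinpath(name).read_text()
    config = simulation_config_from_dict(yaml.safe_load(text))
    if seed is not None:
        config.seed = int(seed)
    return config


def thrombin_timelapse_config(seed: int | None = None) -> SimulationConfig:
    """Aptamer + control two-spot detection time lapse."""
    return _load("thrombin_timelapse.yaml", seed)


def height_series_config(seed: int | None = None) -> SimulationConfig:
    """Single sub-saturation heterogeneous grating."""
    return _load("height_series.yaml", seed)


def rois_from_config(config: SimulationConfig) -> dict[str, tuple[int, int, int, int]]:
    """Per-spot analysis regions (the printed spot rectangles).

    In a real experiment these are the regions a user draws around each
    printed grating; for simulated scenes the print geometry is known.
    """
    return {spot.name: spot.region for spot in config.spots}
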