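"""File I/O: TIFF stacks and images, YAML configs, ground-truth sidecars.

Intensities are float arbitrary units in [0, 1] in memory and 16-bit
unsigned integers on disk; reading rescales by the file's bit depth.
Frame timestamps travel in a JSON sidecar next to the stack.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .simulate import (
    BindingParams,
    GroundTruth,
    ImageStack,
    OpticsParams,
    SimulationConfig,
    SpotSpec,
)

__all__ = [
    "write_stack",
    "read_stack",
    "write_image",
    "read_image",
    "write_ground_truth",
    "read_ground_truth_amplitudes",
    "load_simulation_config",
    "save_simulation_config",
    "simulation_config_from_dict",
    "simulation_config_to_dict",
]

_SCALE = {np.uint8: 255.0, np.uint16: 65535.0}


def _to_uint16(arr: np.ndarray) -> np.ndarray:
    return np.round(np.clip(arr, 0.0, 1.0) * 65535.0).astype(np.uint16)


def _from_integer(arr: np.ndarray) -> np.ndarray:
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    if np.issubdtype(arr.dtype, np.floating):
        return arr.astype(float)
    raise ValueError(f"unsupported TIFF dtype {arr.dtype}; expected uint8, uint16 or float")


def _sidecar_path(stack_path: Path) -> Path:
    return stack_path.with_suffix(stack_path.suffix + ".json")


def write_stack(path, stack: ImageStack) -> Path:
    """Write a multi-page RGB 16-bit TIFF plus a JSON timing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, _to_uint16(stack.frames), photometric="rgb")
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps({"times_min": stack.times_min.tolist()}, indent=2))
    return path


def read_stack(path, frame_rate_per_min: float | None = None) -> ImageStack:
    """Read a multi-page RGB TIFF into an :class:`ImageStack`.

    Frame times come from the JSON sidecar written by :func:`write_stack`;
    without one, ``frame_rate_per_min`` must be given and times are derived
    from it.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 3:
        arr = arr[None]  # single RGB frame
    if arr.ndim != 4 or arr.shape[-1] != 3:
        raise ValueError(
            f"{path}: expected a multi-page RGB stack (T, rows, cols, 3), got shape {arr.shape}"
        )
    frames = _from_integer(arr)
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        times = np.asarray(json.loads(sidecar.read_text())["times_min"], dtype=float)
        if len(times) != frames.shape[0]:
            raise ValueError(f"{sidecar}: timing sidecar length does not match frame count")
    elif frame_rate_per_min is not None:
        times = np.arange(frames.shape[0]) / float(frame_rate_per_min)
    else:
        raise ValueError(
            f"{path}: no timing sidecar found and no frame_rate_per_min given"
        )
    return ImageStack(frames=frames, times_min=times)


def write_image(path, image: np.ndarray) -> Path:
    """Write a single-channel float image as a 16-bit TIFF."""
    path = Path(path)
    tifffile.imwrite(path, _to_uint16(np.asarray(image)))
    return path


def read_image(path) -> np.ndarray:
    """Read a single-channel TIFF as float in [0, 1]."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-channel image, got shape {arr.shape}")
    return _from_integer(arr)


def write_ground_truth(out_dir, truth: GroundTruth) -> None:
    """Write ground truth: JSON summary plus label/height/mask TIFFs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta = {
        "injected_amplitudes": truth.injected_amplitudes,
        "n_bragg_pixels": int(truth.height_map.bragg_truth.sum()),
        "n_scatter_pixels": int(truth.scatter_mask.sum()),
        "n_defect_pixels": int(truth.defect_mask.sum()),
    }
    (out_dir / "ground_truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    tifffile.imwrite(out_dir / "spot_labels.tif", truth.height_map.spot_label.astype(np.int16))
    tifffile.imwrite(out_dir / "height_nm.tif", truth.height_map.h.astype(np.float32))
    tifffile.imwrite(out_dir / "bragg_truth.tif", truth.height_map.bragg_truth.astype(np.uint8) * 255)
    tifffile.imwrite(out_dir / "scatter_mask.tif", truth.scatter_mask.astype(np.uint8) * 255)
    tifffile.imwrite(out_dir / "defect_mask.tif", truth.defect_mask.astype(np.uint8) * 255)


def read_ground_truth_amplitudes(out_dir) -> dict[str, float]:
    meta = json.loads((Path(out_dir) / "ground_truth.json").read_text())
    return meta["injected_amplitudes"]


def simulation_config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["image_shape"] = list(config.image_shape)
    d["optics"]["scatter_level_range"] = list(config.optics.scatter_level_range)
    for spot in d["spots"]:
        spot["region"] = list(spot["region"])
        spot["defect_level_range"] = list(spot["defect_level_range"])
    return d


def simulation_config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    spots = []
    for sd in d.pop("spots", []):
        sd = dict(sd)
        resp = sd.pop("response", {})
        spots.append(
            SpotSpec(
                name=sd.pop("name"),
                region=tuple(sd.pop("region")),
                median_height_nm=float(sd.pop("median_height_nm")),
                response=BindingParams(**resp),
                **{
                    k: (tuple(v) if k == "defect_level_range" else v)
                    for k, v in sd.items()
                },
            )
        )
    optics = d.pop("optics", {})
    if "scatter_level_range" in optics:
        optics = dict(optics)
        optics["scatter_level_range"] = tuple(optics["scatter_level_range"])
    return SimulationConfig(
        image_shape=tuple(d.pop("image_shape", (128, 128))),
        spots=spots,
        optics=OpticsParams(**optics),
        **d,
    )


def load_simulation_config(path) -> SimulationConfig:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"simulation config not found: {path}")
    return simulation_config_from_dict(yaml.safe_load(path.read_text()))


def save_simulation_config(path, config: SimulationConfig) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(simulation_config_to_dict(config), sort_keys=False))
    return path
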