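import dataclasses

import numpy as np
import pytest

from braggsense import BindingParams, OpticsParams, SimulationConfig, SpotSpec


def make_config(
    *,
    shape=(48, 48),
    region=(8, 8, 40, 40),
    median_nm=45.0,
    sigma_log=0.15,
    amplitude=0.2,
    rate_per_min=0.6,
    height_scaling=True,
    background=0.01,
    noise_sd=0.0,
    scatter_fraction=0.1,
    defect_fraction=0.0,
    defect_noise_sd=0.0,
    seed=0,
    duration_min=20.0,
    frame_rate_per_min=5.0,
    analyte_time_min=5.0,
) -> SimulationConfig:
    """Small single-spot scene; noise-free and defect-free by default."""
    spot = SpotSpec(
        name="aptamer" if amplitude > 0 else "control",
        region=region,
        median_height_nm=median_nm,
        sigma_log=sigma_log,
        functionalized=amplitude > 0,
        response=BindingParams(
            amplitude=amplitude, rate_per_min=rate_per_min, height_scaling=height_scaling
        ),
        defect_fraction=defect_fraction,
        defect_noise_sd=defect_noise_sd,
    )
    return SimulationConfig(
        image_shape=shape,
        duration_min=duration_min,
        frame_rate_per_min=frame_rate_per_min,
        analyte_time_min=analyte_time_min,
        spots=[spot],
        optics=OpticsParams(background_level=background),
        noise_sd=noise_sd,
        scatter_fraction=scatter_fraction,
        seed=seed,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def replace(obj, **kw):
    return dataclasses.replace(obj, **kw)
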