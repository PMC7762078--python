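"""Design-rule arithmetic for lipid multilayer grating sensors.

Two rules of thumb govern these transducers: a printed grating diffracts
efficiently only while its multilayer height stays below about one tenth of
the line width, and a color camera reading an array optically gives one
independent assay per pixel.
"""

from __future__ import annotations

#: Empirical upper bound on grating height as a fraction of line width.
MAX_HEIGHT_TO_LINE_WIDTH = 0.1


def max_grating_height(line_width_nm: float) -> float:
    """Height (nm) at which diffraction efficiency saturates for a given line width."""
    if not line_width_nm > 0:
        raise ValueError("line_width_nm must be > 0")
    return MAX_HEIGHT_TO_LINE_WIDTH * line_width_nm


def thickness_ratio(multilayer_thickness_nm: float, line_width_nm: float) -> float:
    """How many times thicker a multilayer film is than the grating height bound.

    Used to compare drop-cast micrometer films against the nanograting
    height ceiling for the same line width.
    """
    if not multilayer_thickness_nm > 0:
        raise ValueError("multilayer_thickness_nm must be > 0")
    return multilayer_thickness_nm / max_grating_height(line_width_nm)


def multiplexing_capacity(megapixels: float) -> float:
    """Number of independent single-pixel assays a detector can read out."""
    if not megapixels > 0:
        raise ValueError("megapixels must be > 0")
    return megapixels * 1e6
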