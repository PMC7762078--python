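"""Refine the Bragg mask to pixels consistent with the height-diffraction law.

Fluorescence of the dye-doped lipid is proportional to multilayer height,
so binning by fluorescence bins by height.  Within each bin, pixels whose
initial diffraction intensity strays more than one standard deviation from
the bin mean — print defects, contaminated pixels — are dropped.
"""

import numpy as np

import braggsense as bs

config = bs.height_series_config(seed=0)
stack, fluorescence, truth = bs.simulate_timelapse(config)

baseline = np.flatnonzero(stack.times_min <= config.analyte_time_min)
green0 = stack.frames[baseline, :, :, 1].mean(axis=0)
red0 = stack.frames[baseline, :, :, 0].mean(axis=0)

mask = bs.threshold_bragg(bs.ratio_image(green0, red0), bs.suggest_threshold(bs.ratio_image(green0, red0)))
refined, stats = bs.sd_band_select(green0, fluorescence, mask, n_bins=10, k_sd=1.0)
fit = bs.fit_height_diffraction(green0, fluorescence, refined)

defects_before = (mask.mask & truth.defect_mask).sum()
defects_after = (refined.mask & truth.defect_mask).sum()
print(f"Bragg mask    : {mask.n_pixels} pixels ({defects_before} known defects)")
print(f"SD-band mask  : {refined.n_pixels} pixels ({defects_after} known defects survive)")
print(f"fit           : green0 = {fit.slope:.3f} * fluor + {fit.intercept:.4f}, "
      f"r^2 = {fit.r_squared:.3f} over {fit.n_pixels} pixels")
print(f"expected slope: {config.optics.diffraction_per_nm / config.optics.fluorescence_per_nm:.3f} "
      "(ratio of diffraction to fluorescence coefficients)")
# The SD band removes most anomalous pixels, and the slope of the
# diffraction-vs-fluorescence line recovers the optics coefficient ratio.
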