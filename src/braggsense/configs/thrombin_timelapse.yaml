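# Two-spot thrombin detection time lapse: an aptamer-functionalized grating
# and a non-aptamer control, recorded at 5 frames/min for 20 min with the
# analyte added at 5 min.  Gratings are printed near the maximum useful
# height (line width / 10), so the injected steady-state response of 20%
# is expressed at (almost) full amplitude.
image_shape: [128, 128]
line_width_nm: 300.0
frame_rate_per_min: 5.0
duration_min: 20.0
analyte_time_min: 5.0
noise_sd: 0.005
scatter_fraction: 0.08
seed: 0
optics:
  fluorescence_per_nm: 0.012
  diffraction_per_nm: 0.02
  bragg_green_red_contrast: 4.0
  background_level: 0.01
  scatter_level_range: [0.2, 0.6]
spots:
  - name: aptamer
    region: [20, 20, 60, 108]
    median_height_nm: 45.0
    sigma_log: 0.15
    functionalized: true
    response:
      amplitude: 0.20
      rate_per_min: 0.6
      height_scaling: true
    defect_fraction: 0.08
    defect_noise_sd: 0.05
    defect_level_range: [0.1, 0.9]
  - name: control
    region: [68, 20, 108, 108]
    median_height_nm: 45.0
    sigma_log: 0.15
    functionalized: false
    response:
      amplitude: 0.0
      rate_per_min: 0.6
      height_scaling: true
    defect_fraction: 0.08
    defect_noise_sd: 0.05
    defect_level_range: [0.1, 0.9]
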