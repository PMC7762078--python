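# Single heterogeneous aptamer grating with sub-saturation heights
# (median 12 nm << 30 nm ceiling), used to probe the linear
# height-diffraction relation and the height dependence of the response.
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
    region: [24, 16, 104, 112]
    median_height_nm: 12.0
    sigma_log: 0.3
    functionalized: true
    response:
      amplitude: 0.20
      rate_per_min: 0.6
      height_scaling: true
    defect_fraction: 0.08
    defect_noise_sd: 0.05
    defect_level_range: [0.1, 0.9]
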