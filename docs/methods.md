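# Methods

This note documents the forward model and analysis procedure implemented in
`braggsense`, the parameter choices behind the packaged fixtures, and the
limits of what the synthetic benchmarks demonstrate.

## Forward model

A simulated scene is a pixel grid containing printed grating **spots** on a
dark background. Per spot, per-pixel multilayer heights `h` (nm) are drawn
lognormally (heights are positive and right-skewed, reflecting variable ink
transfer during printing); `sigma_log = 0` yields a uniform-height spot.
Spots must not overlap; background pixels have `h = 0`.

Three optical laws connect height to the recorded images:

* **Fluorescence (height proxy).** `F = c_F·h + b` plus Gaussian noise,
  clipped at zero. `c_F` defaults to 0.012 a.u./nm so that the tallest
  fixture gratings stay inside the unit intensity range.
* **Diffraction.** The green diffracted signal is
  `D(h) = c_D·min(h, w/10)` with line width `w` (default 300 nm, hence a
  30 nm saturation height). The cap is a hard saturation rather than a
  roll-off: the linear-then-flat form is exactly testable and the regime
  above the ceiling is not used quantitatively anywhere downstream.
* **Color contrast.** A Bragg pixel's red and blue channels carry the
  diffracted signal divided by `bragg_green_red_contrast` (default 4), on
  top of a common background offset `b` (default 0.01). Scatter pixels —
  a `scatter_fraction` (default 0.08) of the background — are color-neutral
  with a static brightness drawn from `scatter_level_range` (0.2–0.6).

**Binding kinetics.** The response to analyte addition at `t₀` is
pseudo-first-order, `s(t) = A_eff·(1 − e^{−k(t−t₀)})` for `t ≥ t₀`, zero
before, multiplying the diffracted signal as `D(h)·(1 + s(t))`. For an
analyte concentration far above the dissociation constant the observed rate
is `k ≈ k_on·C`; the fixture value `k = 0.6 min⁻¹` corresponds to a typical
aptamer on-rate of ~10⁴ M⁻¹s⁻¹ at 1 µM, and is consistent with a response
visible within about a minute of addition. With `height_scaling` enabled,
`A_eff = A·min(h/h_max, 1)`: taller gratings (more lipid volume per pixel)
respond proportionally more strongly, saturating at the design ceiling.
Control spots are identical but carry `A = 0` (enforced by validation).

**Defect pixels.** A fraction of each spot's pixels (default 0.08 in the
fixtures) are rendered as anomalous gratings: still green-dominant, but
with a diffraction level drawn uniformly from `defect_level_range`
independent of height, an extra per-frame Gaussian flicker
(`defect_noise_sd = 0.05`), and no analyte response. This population models
the real-world pixels that diffract but do not follow the height law —
regions printed from excess or contaminated ink — and it is the reason
SD-band selection helps: with only i.i.d. additive camera noise, trimming a
band within each bin would merely shrink the averaging mask (the baseline
CV of a mean over N like pixels scales as `1/√N`) and could never reduce
it. The defect population gives the selection step something real to
remove, and the SNR benefit is then measured, not assumed.

**Noise and units.** Additive Gaussian noise (default SD 0.005) per channel
per frame, clipped at zero; shot noise is deliberately omitted. Intensities
are float arbitrary units in [0, 1]; quantization to 16 bits happens only
at file-write time. Acquisition runs `duration_min` at `frame_rate_per_min`
(fixtures: 20 min at 5 frames/min → 101 frames), timestamps in minutes from
the start; the addition time is configuration metadata, never inferred from
the data. All randomness flows from a single integer seed, and identical
configurations reproduce bit-identical stacks.

## Analysis procedure

1. **Initial image.** The pre-addition green and red images are the means
   over all frames with `t ≤ analyte_time_min` (26 frames in the fixtures).
   Averaging suppresses the heavy upper tail of the single-frame ratio
   image caused by near-dark red pixels; a single-frame mode exists in the
   CLI.
2. **Ratio and threshold.** `r = G₀/(R₀ + ε)` with `ε` one 16-bit quantum
   by default (recorded in the result for provenance). The automatic
   threshold is Otsu's split of the ratio histogram after clipping at the
   0.95 quantile — the ceiling then sits near the Bragg mode rather than at
   a dark-pixel outlier, and clipped tail pixels simply count toward the
   high class. The comparison is inclusive (`r ≥ τ`), making ties
   deterministic. A constant ratio image is an error instructing a manual
   τ. The blue channel is ignored in classification but preserved in I/O.
3. **SD band.** Ten equal-width fluorescence bins spanning the masked range
   (last bin right-inclusive); per bin, keep `|G₀ − mean| ≤ k·SD` with the
   sample (n−1) SD and `k = 1`, boundary inclusive; bins with fewer than 3
   pixels are dropped entirely. A residual-based variant (banding on global
   OLS residuals of `G₀` on `F`) is available but not the default, because
   the per-bin rule makes no linearity assumption across bins. Selection is
   always a subset of its input and is not idempotent: re-running on the
   refined mask may legitimately shrink it further as bin statistics
   tighten. Note that with continuous within-bin height spread a ±1 SD band
   necessarily trims bin tails even in noise-free data; retention is exactly
   100% only when the within-bin diffraction spread vanishes (uniform or
   saturated heights, as in the detection fixture).
4. **Sensorgrams.** Mean green over the selected mask per frame; the
   baseline `I₀` is the mean over the pre-addition window (more robust than
   frame 0 alone). Percent change at a query time uses the nearest recorded
   frame, resolving ties to the earlier frame. Query times are expressed as
   minutes of analyte exposure and converted internally. Per-sample traces
   come from intersecting the refined mask with user-supplied rectangular
   ROIs (for simulated scenes, the known print geometry). Reports record
   every effective parameter, pixel counts per stage, and use 0-based
   row-major (row, col) coordinates; identical inputs give byte-identical
   reports.

## Fixtures

* `thrombin_timelapse.yaml` — aptamer + control spots (40×88 px each),
  heights lognormal(median 45 nm, σ_log 0.15): printed above the 30 nm
  saturation so nearly all pixels express the full injected amplitude
  `A = 0.20`; 5 frames/min, 20 min, addition at 5 min. The expected
  measured response at 10 min exposure is slightly below 20%:
  `1 − e^{−6} ≈ 0.9975` of the amplitude, times a factor
  `D/(D + b) ≈ 0.98` from the background offset, times ~0.99 from
  surviving non-responding defect pixels — about 19.3%.
* `height_series.yaml` — one 80×96 px spot, heights lognormal(median 12 nm,
  σ_log 0.3), almost entirely sub-saturation; used for the
  height–diffraction line (expected slope `c_D/c_F = 1.67`) and the
  height-binned response.

## Numerical choices and degenerate inputs

Division hazards are guarded by ε everywhere a channel or frame is a
denominator; `ε = 0` is allowed only when the denominator is strictly
positive, otherwise it is an error. Constant fluorescence collapses binning
to a single bin and makes the regression undefined (error; the pipeline
records the fit as absent). Empty masks, empty baseline windows and
out-of-range query times are errors, not NaNs. Validation collects all
offending configuration fields into one message.

## Scope of the synthetic benchmarks

The generator reproduces the transduction laws the analysis assumes, so
passing tests demonstrates the pipeline's correctness and statistical
behavior under those laws — not performance on real microscopy. Real data
add effects deliberately out of scope: illumination drift and flat-field
error, image registration error between fluorescence and diffraction
channels, shot noise, focus drift, and any electromagnetic grating physics
(the diffraction law here is phenomenological, not RCWA). Kinetic-constant
estimation (K_d, k_on/k_off) from sensorgrams is likewise out of scope.
Replicate counts (20 seeds) and the 128×128 px, 101-frame fixture geometry
were chosen to make the full statistical suite run in seconds on a single
CPU while keeping per-spot pixel counts in the thousands.
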