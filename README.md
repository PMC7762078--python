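# braggsense

Colorimetric diffraction analysis for **lipid multilayer grating biosensors**,
with a ground-truthed synthetic image generator for testing every stage
without experimental data.

Lipid multilayer gratings are periodic arrays of sub-100 nm tall fluid lipid
lines printed on a surface. They diffract incident white light, and when an
analyte (e.g. the protein thrombin binding a DNA aptamer embedded in the
lipid) reshapes the lines, the diffracted intensity changes — a label-free
optical transduction read out with an ordinary RGB camera. The package is
for experimentalists and method developers who need to turn such time-lapse
recordings into quantitative binding signals, and to validate that analysis
chain against known ground truth.

## The analysis

Given an RGB diffraction time lapse and a co-registered fluorescence image
of the dye-doped lipid:

1. **Bragg-pixel classification.** First-order diffraction is green under
   the imaging geometry; broadband scatter is color-neutral. The ratio
   image `r = G / (R + ε)` is therefore bimodal, and pixels with
   `r ≥ τ` (τ from Otsu's threshold by default) are Bragg pixels.
2. **SD-band pixel selection.** Fluorescence intensity `F ∝ h` (multilayer
   height), and diffraction `D(h) = c_D · min(h, w/10)` is linear in height
   up to one tenth of the line width `w`. Binning Bragg pixels by `F` bins
   them by height; within each bin, pixels with
   `|G₀ − mean| ≤ k·SD` (sample SD, `k = 1`) are kept. Pixels that diffract
   anomalously for their height — print defects, contaminated regions — are
   rejected, which is what buys the sensorgram its signal-to-noise ratio.
3. **Sensorgram extraction.** The mean green intensity over the selected
   pixels per frame, baseline-normalized over the pre-addition window,
   gives `ΔI/I₀` in percent at any exposure time, per region of interest
   (sample vs control), plus final/initial change-ratio images and
   height-binned response curves.

The bundled forward model (`simulate_timelapse`) renders scenes obeying
exactly these laws — lognormal per-spot heights, `F = c_F·h + b`,
saturating `D(h)`, green-dominant Bragg pixels, color-neutral scatter, a
pseudo-first-order binding response `A_eff·(1 − e^{−k(t−t₀)})` that can
scale with `h/h_max`, defect pixels, and Gaussian camera noise — and
returns the ground truth needed to score every stage.

## Worked example

```bash
python examples/04_sensorgram.py
```

```
pixels: 16384 total -> 7040 Bragg -> 6577 selected
percent change after 5 min exposure: aptamer +18.41%, control -0.02%
percent change after 10 min exposure: aptamer +19.33%, control -0.03%
differential (aptamer - control) at 15 min: +19.35%
```

The packaged detection fixture injects a 20% steady-state response into the
aptamer grating (rate 0.6 min⁻¹, analyte added at 5 min) and none into the
control. The pipeline recovers +19.3% at 10 min exposure — slightly below
the injected amplitude because of the finite approach rate, the camera
background offset, and residual defect pixels — while the control stays at
the noise floor. The other examples cover simulation (`01`), Bragg masking
with precision/recall against ground truth (`02`), SD-band selection and
the height–diffraction fit (`03`), and the height-binned response (`05`).

A thin CLI mirrors the library: `braggsense simulate | bragg-mask | select |
sensorgram | run` (see `--help` on each verb).

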