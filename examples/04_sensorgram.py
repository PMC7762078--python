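"""Extract aptamer and control sensorgrams and their percent change.

Runs the full pipeline on the detection fixture and reports the percent
change in mean green diffraction 10 minutes after analyte addition, for
the aptamer grating and the non-aptamer control.
"""

import braggsense as bs

config = bs.thrombin_timelapse_config(seed=0)
stack, fluorescence, _ = bs.simulate_timelapse(config)

result = bs.analyze(
    stack, fluorescence,
    analyte_time_min=config.analyte_time_min,
    rois=bs.rois_from_config(config),
    t_query_min_after_addition=(5.0, 10.0),
)

counts = result.report["pixel_counts"]
print(f"pixels: {counts['total']} total -> {counts['bragg_mask']} Bragg -> {counts['sd_band']} selected")
for dt, per_sample in result.report["percent_change_at_min_after_addition"].items():
    line = ", ".join(f"{label} {pct:+.2f}%" for label, pct in per_sample.items())
    print(f"percent change after {dt} min exposure: {line}")

s_apt = result.sensorgrams["aptamer"]
s_ctl = result.sensorgrams["control"]
t_query = config.analyte_time_min + 10.0
diff = bs.compare_to_control(s_apt, s_ctl, t_query)
print(f"differential (aptamer - control) at {t_query:g} min: {diff:+.2f}%")
# The aptamer grating rises toward the injected 20% steady-state response;
# the control stays flat, so the differential is the specific signal.
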