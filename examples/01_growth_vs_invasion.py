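"""Separate 3D growth from invasion in a simulated acinus time-lapse.

Simulates a non-invasive (control) and an invasive cohort of acini imaged
hourly, segments every frame, reduces the movies to 12-h blocks and reports
block area (growth) and block compactness (protrusiveness), Z-scored to the
control with one-way ANOVA p-values.
"""

import morphoquant as mq
from morphoquant.workflows import growth_invasion_screen

conditions = {
    "control": mq.AcinusSimParams(n_acini=30, n_frames=48, growth_rate=0.25, seed=1),
    "invasive": mq.AcinusSimParams(
        n_acini=30, n_frames=48, growth_rate=0.25, protrusion_rate=0.5, seed=2
    ),
}

blocks, normed, summary = growth_invasion_screen(conditions, control="control")

print("Per-condition mean block metrics (final 12-h block):")
final = blocks[blocks["block_index"] == blocks["block_index"].max()]
print(final.groupby("condition")[["area_px2", "compactness"]].mean().round(3))
print()
print("Z-scored to control with one-way ANOVA against control:")
print(summary.round(4).to_string(index=False))
print()
print(
    "Both cohorts grow (area increases), but only the invasive cohort's\n"
    "compactness rises above the disc value of 1 — the protrusion footprint\n"
    "in the 12-h union image, quantifying invasion independently of growth."
)
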