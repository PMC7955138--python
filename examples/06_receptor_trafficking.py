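"""Receptor-uptake redistribution: membrane band to juxtanuclear ring.

Simulates a labelled-receptor internalisation assay in which surface signal
moves to a perinuclear compartment over 30 minutes, and profiles the
region/whole-cell intensity ratios per timepoint.
"""

import morphoquant as mq

params = mq.TraffickingSimParams(n_cells=20, seed=3)
series = mq.generate_trafficking_series(params)
profile = mq.trafficking_profile(series, normalise="zscore")

agg = (
    profile.groupby(["time_h", "region"])["ratio"]
    .mean()
    .unstack()[["peripheral", "cytoplasm", "juxtanuclear"]]
)
print("mean region / whole-cell intensity ratio per timepoint (h):")
print(agg.round(3))
print()
print(
    "The membrane (peripheral) ratio falls while the juxtanuclear ratio\n"
    "rises, recovering the simulated internalisation itinerary; Z-scored\n"
    "ratios (z_ratio column) are what a multi-condition comparison plots."
)
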