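"""Two-channel spot colocalization: % of green spot area over red spots.

Builds punctate scenes with a known true overlap fraction, detects spots in
both rendered channels and reports the per-cell green-in-red overlap — the
readout used for GTP-loaded ARF (sensor spots over tagged-ARF spots).
"""

import morphoquant as mq

for fraction in (0.0, 0.5, 1.0):
    scene = mq.generate_spot_scene(
        mq.SpotSceneParams(true_overlap_fraction=fraction, seed=7)
    )
    g_labels, _ = mq.detect_spots(scene.green, scene.cells)
    r_labels, _ = mq.detect_spots(scene.red, scene.cells)
    measured = mq.spot_overlap(g_labels, r_labels, scene.cells)
    truth = scene.truth["percent_overlap"].mean()
    print(
        f"true overlap {100 * fraction:5.1f}% | recorded truth {truth:5.1f}% | "
        f"measured from rendered channels {measured['percent_overlap'].mean():5.1f}%"
    )

print()
print(
    "Measured per-cell overlap tracks the constructed ground truth. The\n"
    "statistic is directional: green-in-red, not red-in-green."
)
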