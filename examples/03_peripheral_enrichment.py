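"""Quantify peripheral (membrane-proximal) marker enrichment per cell.

Generates fixed-cell scenes with known peripheral enrichment of a marker
(e.g. a phosphoinositide probe) and measures the mean peripheral / mean
whole-cell intensity ratio inside a 5-px periphery.
"""

import numpy as np

import morphoquant as mq

for enrichment in (1.0, 2.0, 4.0):
    scene = mq.generate_cell_scene(
        mq.CellSceneParams(n_cells=10, peripheral_enrichment=enrichment, seed=5)
    )
    ratios = []
    for lab in scene.truth["cell"]:
        rm = mq.build_region_masks(
            scene.labels == lab, scene.nuclei_labels == lab, mode="five_px_periphery"
        )
        out = mq.region_intensity(scene.channels["marker"], rm).set_index("region")
        ratios.append(out.loc["peripheral", "ratio_to_whole_cell"])
    print(f"true enrichment {enrichment:.0f}x -> peripheral/total ratio "
          f"{np.mean(ratios):.3f} +/- {np.std(ratios):.3f} (n={len(ratios)})")

print()
print(
    "The measured peripheral-over-total ratio increases monotonically with\n"
    "the generated enrichment; a ratio of 1 means no peripheral bias. The\n"
    "ratio is compressed relative to the raw periphery/interior contrast\n"
    "because the whole-cell mean includes the bright periphery itself."
)
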