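"""Classify single cells into round / spread / spindle shape phenotypes.

Trains the shape classifier on a clean synthetic field of the three
archetypes and recovers the class proportions of an independent field.
"""

import numpy as np

import morphoquant as mq
from morphoquant.morphometry import features_table


def scene_features(n_cells, proportions, seed):
    scene = mq.generate_cell_scene(
        mq.CellSceneParams(n_cells=n_cells, class_proportions=proportions, seed=seed)
    )
    ft = features_table(scene.labels).set_index("label")
    truth = scene.truth.set_index("cell")
    return ft.loc[truth.index].reset_index(drop=True), truth["shape_class"].to_numpy()


Xtr, ytr = scene_features(150, (1 / 3, 1 / 3, 1 / 3), seed=1)
model = mq.train_shape_classifier(Xtr, ytr, seed=0)

Xte, yte = scene_features(200, (0.5, 0.3, 0.2), seed=2)
pred = mq.classify_cells(Xte, model)
acc = np.mean([c.label for c in pred] == yte)

print(f"held-out accuracy: {acc:.3f}")
print("recovered class proportions (true: round 0.50, spread 0.30, spindle 0.20):")
print(mq.class_proportions(pred).round(3).to_string())
print()
print(
    "Accuracy near 1 and proportions near the generating simplex show the\n"
    "7 shape features (area, perimeter, compactness, eccentricity, aspect\n"
    "ratio, solidity, form factor) separate the three archetypes."
)
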