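"""Shape features for size/protrusiveness readouts and the three-way
round / spread / spindle phenotype classifier.

The central statistic is a moment-based *compactness*,

    compactness = 2*pi * <r^2> / area,

where ``<r^2>`` is the mean squared pixel distance from the object centroid.
A filled disc scores 1 and any mass displaced outward — e.g. into invasive
protrusions — raises the score, which is what makes it a protrusiveness
measure that is independent of object size.
"""

from __future__ import annotations

from dataclasses import dataclass

import joblib
import numpy as np
import pandas as pd
from skimage import measure
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .synthetic import SHAPE_CLASSES

__all__ = [
    "FEATURE_COLUMNS",
    "ShapeClass",
    "compactness",
    "shape_features",
    "features_table",
    "ShapeClassifier",
    "train_shape_classifier",
    "classify_cells",
]

FEATURE_COLUMNS = (
    "area",
    "perimeter",
    "compactness",
    "eccentricity",
    "aspect_ratio",
    "solidity",
    "form_factor",
)


@dataclass
class ShapeClass:
    label: str
    confidence: float


def compactness(mask: np.ndarray) -> float:
    """Moment-based compactness of a boolean mask (filled disc = 1)."""
    ys, xs = np.nonzero(np.asarray(mask, bool))
    if ys.size == 0:
        raise ValueError("empty mask")
    cy, cx = ys.mean(), xs.mean()
    msd = ((ys - cy) ** 2 + (xs - cx) ** 2).mean()
    return float(2.0 * np.pi * msd / ys.size)


def _features_from_region(region, mask_bool: np.ndarray, pixel_size: float) -> dict:
    minor = region.axis_minor_length
    major = region.axis_major_length
    per = region.perimeter
    return {
        "area": float(region.area),
        "area_um2": float(region.area) * pixel_size**2,
        "perimeter": float(per),
        "compactness": compactness(mask_bool),
        "eccentricity": float(region.eccentricity),
        "aspect_ratio": float(major / minor) if minor > 0 else float("inf"),
        "solidity": float(region.solidity),
        "form_factor": float(4.0 * np.pi * region.area / per**2) if per > 0 else 1.0,
        "centroid_y": float(region.centroid[0]),
        "centroid_x": float(region.centroid[1]),
    }


def shape_features(mask: np.ndarray, label: int, pixel_size: float = 1.0) -> dict:
    """Shape features of one labelled object.

    Raises ``KeyError`` if ``label`` is absent from the mask.
    """
    mask = np.asarray(mask)
    sub = mask == label
    if not sub.any():
        raise KeyError(f"label {label} not present in mask")
    region = measure.regionprops(sub.astype(np.uint8))[0]
    out = _features_from_region(region, sub, pixel_size)
    out["label"] = int(label)
    return out


def features_table(mask: np.ndarray, pixel_size: float = 1.0) -> pd.DataFrame:
    """Shape-feature table with one row per labelled object."""
    mask = np.asarray(mask)
    rows = []
    for region in measure.regionprops(mask):
        sub = mask == region.label
        row = _features_from_region(region, sub, pixel_size)
        row["label"] = int(region.label)
        rows.append(row)
    cols = ["label", *FEATURE_COLUMNS, "area_um2", "centroid_y", "centroid_x"]
    return pd.DataFrame(rows, columns=cols) if rows else pd.DataFrame(columns=cols)


@dataclass
class ShapeClassifier:
    """Standardised multinomial logistic model over the 7 shape features."""

    pipeline: Pipeline
    feature_columns: tuple[str, ...]
    classes_: tuple[str, ...]
    seed: int

    def predict(self, features: pd.DataFrame) -> list[ShapeClass]:
        return classify_cells(features, self)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ShapeClassifier":
        return joblib.load(path)


def _feature_matrix(features: pd.DataFrame, columns) -> np.ndarray:
    missing = [c for c in columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns {missing}")
    X = features.loc[:, list(columns)].to_numpy(float)
    # infinite aspect ratios (degenerate thin objects) are capped, not dropped
    return np.nan_to_num(X, posinf=1e6, neginf=-1e6)


def train_shape_classifier(
    features: pd.DataFrame,
    labels,
    seed: int = 0,
    feature_columns=FEATURE_COLUMNS,
) -> ShapeClassifier:
    """Fit the round/spread/spindle classifier.

    Requires at least two distinct classes with >= 5 examples each. Training
    is deterministic given (data, seed) and the fitted model serialises with
    its feature schema embedded.
    """
    labels = np.asarray(labels, dtype=object)
    if len(labels) != len(features):
        raise ValueError("features and labels length mismatch")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least two classes to train")
    if counts.min() < 5:
        raise ValueError("need at least 5 examples per class")
    X = _feature_matrix(features, feature_columns)
    pipe = Pipeline(
        [
            ("scale", StandardScaler()),
            ("clf", LogisticRegression(max_iter=2000, random_state=seed)),
        ]
    )
    pipe.fit(X, labels)
    return ShapeClassifier(
        pipeline=pipe,
        feature_columns=tuple(feature_columns),
        classes_=tuple(pipe.named_steps["clf"].classes_),
        seed=seed,
    )


def classify_cells(features: pd.DataFrame, model: ShapeClassifier) -> list[ShapeClass]:
    """Predict one ShapeClass (label + probability) per feature row.

    Probability ties are broken by canonical class order round < spread <
    spindle.
    """
    if len(features) == 0:
        return []
    X = _feature_matrix(features, model.feature_columns)
    proba = model.pipeline.predict_proba(X)
    order = {c: SHAPE_CLASSES.index(c) if c in SHAPE_CLASSES else 99 for c in model.classes_}
    out = []
    for row in proba:
        best = max(
            range(len(row)),
            key=lambda i: (row[i], -order[model.classes_[i]]),
        )
        out.append(ShapeClass(label=str(model.classes_[best]), confidence=float(row[best])))
    return out


def class_proportions(classes) -> pd.Series:
    """Fraction of objects per predicted class (0 for absent classes).

    Accepts ShapeClass instances or bare label strings.
    """
    labels = [c.label if isinstance(c, ShapeClass) else str(c) for c in classes]
    counts = pd.Series(labels, dtype=object).value_counts()
    return counts.reindex(SHAPE_CLASSES, fill_value=0) / max(len(classes), 1)
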