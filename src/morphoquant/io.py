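"""TIFF / CSV / JSON sidecar export for scenes, masks and result tables."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .containers import TimeLapse

__all__ = [
    "write_timelapse_tiff",
    "read_timelapse_tiff",
    "write_label_tiff",
    "write_scene",
]


def write_timelapse_tiff(path, tl: TimeLapse) -> None:
    """One TIFF page per frame; calibration in the ImageJ-style metadata."""
    frames = tl.frames
    if frames.dtype == bool:
        frames = frames.astype(np.uint8)
    tifffile.imwrite(
        path,
        frames,
        photometric="minisblack",
        metadata={
            "axes": "TYX",
            "pixel_size_um": tl.pixel_size,
            "frame_interval_h": tl.frame_interval,
        },
    )


def read_timelapse_tiff(path) -> TimeLapse:
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    return TimeLapse(
        frames,
        pixel_size=float(meta.get("pixel_size_um", 1.0)),
        frame_interval=float(meta.get("frame_interval_h", 1.0)),
    )


def write_label_tiff(path, labels: np.ndarray) -> None:
    """16-bit label-mask TIFF (0 = background)."""
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(path, labels.astype(np.uint16))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (tuple, list)):
        return [_jsonable(v) for v in obj]
    return obj


def write_scene(directory, name: str, images: dict[str, np.ndarray],
                truth: pd.DataFrame | None = None, params=None) -> Path:
    """Write a generated scene: multi-channel TIFF, truth CSV, params JSON.

    Channels are stacked in sorted name order into one multi-page TIFF.
    Returns the scene directory.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    order = sorted(images)
    stack = np.stack([np.asarray(images[k], dtype=np.float32) for k in order])
    tifffile.imwrite(
        directory / f"{name}.tif",
        stack,
        photometric="minisblack",
        metadata={"axes": "CYX", "channels": order},
    )
    if truth is not None:
        truth.to_csv(directory / f"{name}_truth.csv", index=False)
    if params is not None:
        with open(directory / f"{name}_params.json", "w") as fh:
            json.dump(_jsonable(params), fh, indent=2, sort_keys=True)
    return directory
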