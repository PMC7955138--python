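"""Time-lapse reduction: colour-time overlays, 12-h block metrics and the
wound-assay relative wound density (RWD) readout.

Hourly acinus imaging is reduced to one measurement per 12-h block: object
masks from every frame in a block are combined (pixel union by default) and
area/compactness of the combined footprint are reported. Growth moves block
area while leaving compactness near the disc value of 1; invasive protrusion
leaves a flared cumulative footprint that raises compactness — this is how
growth and invasion are quantified separately from the same movie.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from matplotlib.colors import hsv_to_rgb
from scipy.spatial.distance import cdist
from skimage import measure, segmentation as skseg

from .containers import TimeLapse
from .morphometry import compactness

__all__ = [
    "colour_time_overlay",
    "track_objects",
    "block_metrics",
    "rwd_course",
    "tmax_half",
    "TMaxHalf",
]


def colour_time_overlay(masks: list[np.ndarray]) -> np.ndarray:
    """Render per-frame object outlines on a blue-to-red time ramp.

    Frame ``i`` of ``n`` is painted with HSV hue interpolated from blue
    (i = 0) to red (i = n-1); later frames are drawn over earlier ones.
    Returns an (H, W, 3) float RGB image; raises on an empty block.
    """
    if len(masks) == 0:
        raise ValueError("empty block: no masks to overlay")
    h, w = np.asarray(masks[0]).shape
    rgb = np.zeros((h, w, 3), dtype=np.float64)
    n = len(masks)
    for i, m in enumerate(masks):
        frac = 0.0 if n == 1 else i / (n - 1)
        hue = (2.0 / 3.0) * (1.0 - frac)          # 2/3 = blue ... 0 = red
        colour = hsv_to_rgb([hue, 1.0, 1.0])
        outline = skseg.find_boundaries(np.asarray(m) > 0, mode="inner")
        rgb[outline] = colour
    return rgb


def track_objects(masks: list[np.ndarray], max_move: float = 15.0) -> list[pd.DataFrame]:
    """Assign stable track ids across frames by greedy centroid linking.

    Suited to sessile objects (acini); returns one table per frame with
    ``label``, ``centroid_y/x`` and ``track`` columns.
    """
    tables = []
    prev = None
    next_track = 1
    for m in masks:
        rows = [
            {
                "label": r.label,
                "centroid_y": r.centroid[0],
                "centroid_x": r.centroid[1],
            }
            for r in measure.regionprops(np.asarray(m))
        ]
        t = pd.DataFrame(rows, columns=["label", "centroid_y", "centroid_x"])
        t["track"] = 0
        if prev is not None and len(prev) and len(t):
            d = cdist(
                prev[["centroid_y", "centroid_x"]].to_numpy(float),
                t[["centroid_y", "centroid_x"]].to_numpy(float),
            )
            cand = sorted(
                (d[i, j], i, j)
                for i in range(len(prev))
                for j in range(len(t))
                if d[i, j] <= max_move
            )
            ta, tb = set(), set()
            for _, i, j in cand:
                if i in ta or j in tb:
                    continue
                ta.add(i)
                tb.add(j)
                t.loc[t.index[j], "track"] = prev.iloc[i]["track"]
        for j in t.index[t["track"] == 0]:
            t.loc[j, "track"] = next_track
            next_track += 1
        tables.append(t)
        prev = t
    return tables


def block_metrics(
    masks: list[np.ndarray],
    block_hours: float = 12.0,
    frame_interval: float = 1.0,
    method: str = "union",
    pixel_size: float = 1.0,
    well: str | None = None,
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Area and compactness per object per 12-h block.

    ``method='union'`` (default) measures the pixel union of each object's
    masks across the block — the cumulative footprint, capturing transient
    protrusions. ``method='median'`` instead reports the per-frame median of
    the metrics within the block. A trailing block covering fewer frames
    than a full block is computed but flagged ``partial``.

    Returns ``(table, block_union_masks)``; the table has one row per
    (track, block).
    """
    if method not in ("union", "median"):
        raise ValueError("method must be 'union' or 'median'")
    n_per_block = max(1, int(round(block_hours / frame_interval)))
    tracked = track_objects(masks)
    rows = []
    block_masks: dict[int, np.ndarray] = {}
    n_blocks = math.ceil(len(masks) / n_per_block)
    for b in range(n_blocks):
        frames = list(range(b * n_per_block, min((b + 1) * n_per_block, len(masks))))
        partial = len(frames) < n_per_block
        union_all = np.zeros_like(np.asarray(masks[0]), dtype=bool)
        per_track: dict[int, list] = {}
        for f in frames:
            m = np.asarray(masks[f])
            union_all |= m > 0
            for _, r in tracked[f].iterrows():
                per_track.setdefault(int(r["track"]), []).append((f, int(r["label"])))
        block_masks[b] = union_all
        for track, items in sorted(per_track.items()):
            if method == "union":
                u = np.zeros_like(union_all)
                for f, lab in items:
                    u |= np.asarray(masks[f]) == lab
                area = int(u.sum())
                comp = compactness(u) if area else math.nan
            else:
                areas, comps = [], []
                for f, lab in items:
                    sub = np.asarray(masks[f]) == lab
                    areas.append(int(sub.sum()))
                    comps.append(compactness(sub))
                area = float(np.median(areas))
                comp = float(np.median(comps))
            rows.append(
                {
                    "well": well,
                    "block_index": b,
                    "track": track,
                    "area_px2": area,
                    "area_um2": area * pixel_size**2,
                    "compactness": comp,
                    "n_frames": len(items),
                    "partial": partial,
                }
            )
    cols = ["well", "block_index", "track", "area_px2", "area_um2", "compactness", "n_frames", "partial"]
    return pd.DataFrame(rows, columns=cols), block_masks


def rwd_course(
    wound_masks: TimeLapse | list[np.ndarray],
    initial_wound: np.ndarray | None = None,
    times: np.ndarray | None = None,
) -> pd.DataFrame:
    """Relative wound density over time from confluence masks.

    RWD(t) = 100 * (w(t) - w(0)) / (c(t) - w(0)), where ``w`` is the
    confluent-pixel fraction inside the initial wound region and ``c`` the
    fraction outside it; clipped to [0, 100]. Rows where the outer density
    does not exceed the initial wound density are flagged ``undefined``.
    """
    if isinstance(wound_masks, TimeLapse):
        if times is None:
            times = wound_masks.times
        frames = [np.asarray(f, bool) for f in wound_masks.frames]
    else:
        frames = [np.asarray(f, bool) for f in wound_masks]
        if times is None:
            times = np.arange(len(frames), dtype=float)
    if initial_wound is None:
        initial_wound = ~frames[0]
    initial_wound = np.asarray(initial_wound, bool)
    if not initial_wound.any() or initial_wound.all():
        raise ValueError("initial wound region must be a strict subset of the field")
    outer = ~initial_wound
    w0 = float(frames[0][initial_wound].mean())
    rows = []
    for t, fr in zip(times, frames):
        w = float(fr[initial_wound].mean())
        c = float(fr[outer].mean())
        undefined = c <= w0
        rwd = math.nan if undefined else float(np.clip(100.0 * (w - w0) / (c - w0), 0.0, 100.0))
        rows.append(
            {
                "time_h": float(t),
                "wound_density": w,
                "cell_region_density": c,
                "rwd": rwd,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)


class TMaxHalf(float):
    """Time (h) at which mean control RWD first reaches 50%; ``reached``
    is False (and the value NaN) if the courses plateau below 50%."""

    reached: bool

    def __new__(cls, value: float, reached: bool):
        obj = super().__new__(cls, value)
        obj.reached = reached
        return obj


def tmax_half(control_courses: list[pd.DataFrame], threshold: float = 50.0) -> TMaxHalf:
    """First time the mean control RWD reaches the 50% threshold.

    The crossing is linearly interpolated between frames. Requires courses
    sampled on a common time grid.
    """
    if not control_courses:
        raise ValueError("need at least one control course")
    times = control_courses[0]["time_h"].to_numpy(float)
    vals = np.mean([c["rwd"].to_numpy(float) for c in control_courses], axis=0)
    for i, v in enumerate(vals):
        if v >= threshold:
            if i == 0 or math.isnan(vals[i - 1]):
                return TMaxHalf(float(times[i]), True)
            t0, t1 = times[i - 1], times[i]
            v0, v1 = vals[i - 1], vals[i]
            frac = (threshold - v0) / (v1 - v0) if v1 != v0 else 0.0
            return TMaxHalf(float(t0 + frac * (t1 - t0)), True)
    return TMaxHalf(math.nan, False)
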