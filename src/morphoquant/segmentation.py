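"""Object segmentation: acini in phase-like frames, nucleus-seeded cells,
cross-plane object matching and per-object plane selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial.distance import cdist
from skimage import filters, measure, morphology, segmentation as skseg

__all__ = [
    "SegConfig",
    "segment_acini",
    "segment_cells",
    "match_objects_across_planes",
    "select_plane_per_object",
]


@dataclass
class SegConfig:
    """Segmentation configuration.

    ``match_upper_bound`` is the Euclidean centroid-distance cut-off (px) for
    linking the same object across consecutive focal planes.
    """

    min_object_area: int = 64
    smoothing_sigma: float = 2.0
    threshold_method: str = "otsu"     # "otsu" | "fixed"
    fixed_threshold: float | None = None
    exclude_border: bool = True
    positivity_channel: str | None = None
    positivity_threshold: float = 0.0
    plane_rule: str = "max_area"       # "max_area" | "mean_of_planes"
    match_upper_bound: float = 5.0

    def __post_init__(self):
        if self.min_object_area < 1:
            raise ValueError("min_object_area must be >= 1")
        if self.match_upper_bound <= 0:
            raise ValueError("match_upper_bound must be > 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required with threshold_method='fixed'")


def _relabel(mask: np.ndarray) -> np.ndarray:
    """Relabel a label mask to contiguous 1..N (stable raster order)."""
    out, _, _ = skseg.relabel_sequential(mask)
    return out.astype(np.int32)


def _threshold_with_guard(dev: np.ndarray, smooth: np.ndarray, cfg: SegConfig) -> np.ndarray | None:
    """Otsu on the smoothed deviation image, rejecting noise-only frames.

    On a frame with no objects Otsu still splits the noise roughly in half;
    the guard requires a foreground/background separation several times the
    background spread before accepting any foreground.
    """
    if cfg.threshold_method == "fixed":
        return smooth > cfg.fixed_threshold
    thr = filters.threshold_otsu(smooth)
    fg = smooth > thr
    if not fg.any() or fg.all():
        return None
    bg = smooth[~fg]
    sep = smooth[fg].mean() - bg.mean()
    if sep < 4.0 * max(bg.std(), 1e-12):
        return None
    return fg


def segment_acini(frame: np.ndarray, cfg: SegConfig | None = None) -> np.ndarray:
    """Segment acinus bodies from one phase-contrast-like frame.

    Phase-like objects have a dark body and a bright halo ring just outside
    it; segmenting the below-background component recovers the body without
    annexing the halo, so measured areas track the true object area.
    Returns an int label mask with contiguous labels 1..N; a noise-only
    frame yields an empty (all-zero) mask.
    """
    cfg = cfg or SegConfig()
    frame = np.asarray(frame, dtype=np.float64)
    if frame.ndim != 2:
        raise ValueError("segment_acini expects a single-channel 2D frame")
    below = np.clip(np.median(frame) - frame, 0.0, None)
    smooth = ndi.gaussian_filter(below, cfg.smoothing_sigma)
    fg = _threshold_with_guard(below, smooth, cfg)
    if fg is None:
        return np.zeros(frame.shape, dtype=np.int32)
    fg = ndi.binary_fill_holes(fg)
    fg = morphology.remove_small_objects(fg, max_size=cfg.min_object_area - 1)
    if cfg.exclude_border:
        fg = skseg.clear_border(fg)
    labels, _ = ndi.label(fg)
    # area filter again after border clearing may leave gaps in numbering
    for region in measure.regionprops(labels):
        if region.area < cfg.min_object_area:
            labels[labels == region.label] = 0
    return _relabel(labels)


def segment_cells(
    nucleus: np.ndarray,
    body: np.ndarray,
    cfg: SegConfig | None = None,
    marker: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Nucleus-seeded cell segmentation bounded by the body channel.

    Cells are detected from nucleus positions and delimited by the body
    (F-actin / CellMask-like) channel via seeded watershed, so touching cells
    with distinct nuclei are split. Cells touching the image border (when
    ``cfg.exclude_border``) or failing marker positivity (when ``marker`` is
    given and ``cfg.positivity_threshold`` > 0) are discarded together with
    their nuclei. Returns ``(nuclei_labels, cell_labels)`` with matching
    label ids.
    """
    cfg = cfg or SegConfig()
    nucleus = np.asarray(nucleus, dtype=np.float64)
    body = np.asarray(body, dtype=np.float64)
    if nucleus.shape != body.shape:
        raise ValueError("nucleus and body channels must have identical shapes")
    if marker is not None and np.asarray(marker).shape != body.shape:
        raise ValueError("marker channel shape mismatch")

    nuc_s = ndi.gaussian_filter(nucleus, cfg.smoothing_sigma)
    nuc_fg = _threshold_with_guard(nucleus, nuc_s, cfg)
    if nuc_fg is None:
        z = np.zeros(nucleus.shape, dtype=np.int32)
        return z, z.copy()
    nuc_fg = morphology.remove_small_objects(
        ndi.binary_fill_holes(nuc_fg), max_size=max(cfg.min_object_area // 4, 4) - 1
    )
    nuclei, _ = ndi.label(nuc_fg)

    body_s = ndi.gaussian_filter(body, cfg.smoothing_sigma)
    body_fg = _threshold_with_guard(body, body_s, cfg)
    body_fg = np.zeros(body.shape, bool) if body_fg is None else ndi.binary_fill_holes(body_fg)
    body_fg |= nuclei > 0   # a cell always contains its nucleus

    dist = ndi.distance_transform_edt(body_fg)
    cells = skseg.watershed(-dist, markers=nuclei, mask=body_fg)

    keep = set(np.unique(nuclei)) - {0}
    if cfg.exclude_border:
        edge = np.concatenate([cells[0, :], cells[-1, :], cells[:, 0], cells[:, -1]])
        keep -= set(np.unique(edge))
    if marker is not None and cfg.positivity_threshold > 0:
        marker = np.asarray(marker, dtype=np.float64)
        for lab in list(keep):
            if marker[cells == lab].mean() < cfg.positivity_threshold:
                keep.discard(lab)
    for lab in set(np.unique(cells)) - {0} - keep:
        cells[cells == lab] = 0
        nuclei[nuclei == lab] = 0

    # identical contiguous relabelling for the paired masks
    old = sorted(keep)
    lut = np.zeros(int(cells.max()) + 1, dtype=np.int32)
    for new, lab in enumerate(old, start=1):
        lut[lab] = new
    return lut[nuclei], lut[cells]


def match_objects_across_planes(
    tables: list[pd.DataFrame], upper_bound: float = 5.0
) -> pd.DataFrame:
    """Greedy nearest-neighbour linking of objects across consecutive planes.

    Each input table needs ``centroid_x`` / ``centroid_y`` columns. Links are
    formed plane-by-plane in order of increasing centroid distance (ties by
    lowest label/row), never exceeding ``upper_bound`` px, one-to-one within
    a plane pair. Unlinked objects form singleton groups.

    Returns the concatenation of the inputs with added ``plane`` and
    ``group`` columns.
    """
    if len(tables) < 2:
        raise ValueError("need at least two plane tables to match")
    frames = []
    for i, t in enumerate(tables):
        t = t.reset_index(drop=True).copy()
        t["plane"] = i
        frames.append(t)

    group_of: dict[tuple[int, int], int] = {}
    next_group = 0
    for r in range(len(frames[0])):
        group_of[(0, r)] = next_group
        next_group += 1
    for i in range(len(frames) - 1):
        a, b = frames[i], frames[i + 1]
        taken_a: set[int] = set()
        taken_b: set[int] = set()
        if len(a) and len(b):
            d = cdist(
                a[["centroid_y", "centroid_x"]].to_numpy(float),
                b[["centroid_y", "centroid_x"]].to_numpy(float),
            )
            cand = [
                (d[ra, rb], ra, rb)
                for ra in range(len(a))
                for rb in range(len(b))
                if d[ra, rb] <= upper_bound
            ]
            for dist, ra, rb in sorted(cand):
                if ra in taken_a or rb in taken_b:
                    continue
                taken_a.add(ra)
                taken_b.add(rb)
                group_of[(i + 1, rb)] = group_of[(i, ra)]
        for rb in range(len(b)):
            if (i + 1, rb) not in group_of:
                group_of[(i + 1, rb)] = next_group
                next_group += 1

    out = pd.concat(frames, ignore_index=True)
    out["group"] = [group_of[(int(p), int(r))] for p, r in
                    zip(out["plane"], out.groupby("plane").cumcount())]
    return out


def select_plane_per_object(matched: pd.DataFrame, rule: str = "max_area") -> pd.DataFrame:
    """Reduce each matched cross-plane group to a single representative row.

    ``max_area``: the row from the plane with the largest area (ties: lowest
    plane index). ``mean_of_planes``: feature-wise mean of the numeric
    columns (``plane`` reports the lowest contributing plane).
    """
    if matched.empty:
        raise ValueError("empty matched table")
    if rule not in ("max_area", "mean_of_planes"):
        raise ValueError("rule must be 'max_area' or 'mean_of_planes'")
    rows = []
    for g, grp in matched.groupby("group", sort=True):
        if rule == "max_area":
            grp = grp.sort_values(["area", "plane"], ascending=[False, True])
            rows.append(grp.iloc[0])
        else:
            num = grp.mean(numeric_only=True)
            num["plane"] = grp["plane"].min()
            num["group"] = g
            rows.append(num)
    return pd.DataFrame(rows).reset_index(drop=True)
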