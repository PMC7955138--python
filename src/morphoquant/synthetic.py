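"""Seeded synthetic-scene generators with exhaustive ground truth.

Every quantity a downstream stage estimates (object area, shape class,
peripheral enrichment, spot overlap, region intensity fractions, wound area)
is also emitted as ground truth by the generator that created the scene, so
the whole pipeline can be exercised as a parameter-recovery problem without
any real microscopy data.

All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .containers import TimeLapse, RegionMasks

__all__ = [
    "AcinusSimParams",
    "CellSceneParams",
    "SpotSceneParams",
    "WoundSimParams",
    "TraffickingSimParams",
    "CellScene",
    "SpotScene",
    "TraffickingSeries",
    "generate_acinus_timelapse",
    "generate_cell_scene",
    "generate_spot_scene",
    "generate_wound_series",
    "generate_trafficking_series",
]

SHAPE_CLASSES = ("round", "spread", "spindle")


# ---------------------------------------------------------------------------
# rasterisation helpers
# ---------------------------------------------------------------------------

def _disc(shape: tuple[int, int], cy: float, cx: float, r: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


def _capsule(shape, p0, p1, width) -> np.ndarray:
    """Pixels within width/2 of the segment p0 -> p1 (a stadium shape)."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    v = np.array(p1, dtype=float) - np.array(p0, dtype=float)
    L2 = float(v @ v)
    dy = yy - p0[0]
    dx = xx - p0[1]
    if L2 == 0.0:
        d2 = dy**2 + dx**2
    else:
        t = np.clip((dy * v[0] + dx * v[1]) / L2, 0.0, 1.0)
        d2 = (dy - t * v[0]) ** 2 + (dx - t * v[1]) ** 2
    return d2 <= (width / 2.0) ** 2


def _mask_compactness(mask: np.ndarray) -> float:
    """Moment-based compactness (disc = 1) computed directly on pixels."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return math.nan
    cy, cx = ys.mean(), xs.mean()
    msd = ((ys - cy) ** 2 + (xs - cx) ** 2).mean()
    return 2.0 * math.pi * msd / ys.size


def _grid_positions(n: int, spacing: float, margin: float, rng) -> tuple[np.ndarray, tuple[int, int]]:
    """Jittered grid centres for n non-overlapping objects; returns field size."""
    ncol = int(math.ceil(math.sqrt(n)))
    nrow = int(math.ceil(n / ncol))
    h = int(round(2 * margin + nrow * spacing))
    w = int(round(2 * margin + ncol * spacing))
    centres = []
    jmax = min(0.12 * spacing, 3.0)  # capped so neighbours can never touch
    for k in range(n):
        i, j = divmod(k, ncol)
        cy = margin + (i + 0.5) * spacing
        cx = margin + (j + 0.5) * spacing
        jit = rng.uniform(-jmax, jmax, size=2)
        centres.append((cy + jit[0], cx + jit[1]))
    return np.array(centres), (h, w)


# ---------------------------------------------------------------------------
# acinus time-lapse
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcinusSimParams:
    """Parameters of the phase-like acinus time-lapse simulation.

    The defaults emulate hourly imaging of 3D prostate-cancer acini over four
    days: round structures that grow radially and, when ``protrusion_rate>0``,
    extend radial capsule-shaped invasive protrusions.
    """

    n_acini: int = 20
    radius0: float = 10.0            # px, initial acinus radius
    growth_rate: float = 0.25        # px/h radial growth
    protrusion_rate: float = 0.0     # px/h protrusion elongation; 0 = non-invasive
    n_protrusions: int = 3
    protrusion_width: float = 5.0    # px
    frame_interval: float = 1.0      # h
    n_frames: int = 96               # hourly frames over 4 days
    pixel_size: float = 1.241        # µm/px (10x objective scale)
    noise_sd: float = 0.03
    heterogeneity: float = 0.10      # relative spread of per-acinus radius/growth
    field_size: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.heterogeneity < 1):
            raise ValueError("heterogeneity must be in [0, 1)")
        if self.radius0 <= 0:
            raise ValueError("radius0 must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.protrusion_rate < 0:
            raise ValueError("protrusion_rate must be >= 0")
        if self.n_acini < 1:
            raise ValueError("n_acini must be >= 1")


def _acinus_truth_feret(r: float, length: float, width: float, angles: np.ndarray) -> float:
    """Analytic maximum Feret diameter of a disc with radial capsule protrusions."""
    feret = 2.0 * r
    if length > 0 and angles.size:
        tip = r + length
        # farthest protrusion-tip point vs the opposite disc edge
        feret = max(feret, tip + width / 2.0 + r)
        for i in range(angles.size):
            for j in range(i + 1, angles.size):
                d = tip * math.hypot(
                    math.cos(angles[i]) - math.cos(angles[j]),
                    math.sin(angles[i]) - math.sin(angles[j]),
                )
                feret = max(feret, d + width)
    return feret


def generate_acinus_timelapse(params: AcinusSimParams) -> tuple[TimeLapse, pd.DataFrame]:
    """Simulate a phase-contrast-like acinus time-lapse.

    Acini are placed without overlap (raises ``ValueError`` if the requested
    count cannot be placed in the field). Appearance per object: dark interior,
    bright halo ring, Gaussian noise. Returns the time-lapse plus a tidy
    ground-truth table with one row per acinus per frame (true pixel area,
    compactness of the noiseless mask, radius, protrusion length, analytic
    maximum Feret diameter).
    """
    p = params
    rng = np.random.default_rng(p.seed)

    hmax = 1.0 + p.heterogeneity
    r_final = hmax * (p.radius0 + p.growth_rate * p.frame_interval * (p.n_frames - 1))
    ext_final = r_final + (
        p.protrusion_rate * p.frame_interval * (p.n_frames - 1) + p.protrusion_width / 2
        if p.protrusion_rate > 0
        else 0.0
    )
    halo = 3.0
    excl = ext_final + halo
    spacing = 2 * excl + 6
    if p.field_size is None:
        # margin accommodates jitter plus threshold blur so no object touches the border
        centres, (H, W) = _grid_positions(p.n_acini, spacing, excl + 9, rng)
    else:
        H, W = p.field_size
        ncol = max(1, int(W // spacing))
        nrow = max(1, int(H // spacing))
        if ncol * nrow < p.n_acini:
            raise ValueError(
                f"cannot place {p.n_acini} acini without overlap in a "
                f"{p.field_size} field (capacity {ncol * nrow})"
            )
        centres = []
        for k in range(p.n_acini):
            i, j = divmod(k, ncol)
            centres.append(
                (
                    (i + 0.5) * spacing + rng.uniform(-2, 2),
                    (j + 0.5) * spacing + rng.uniform(-2, 2),
                )
            )
        centres = np.array(centres)

    angles = [
        rng.uniform(0, 2 * math.pi) + np.arange(p.n_protrusions) * 2 * math.pi / max(p.n_protrusions, 1)
        for _ in range(p.n_acini)
    ]
    # biological heterogeneity: per-acinus initial radius, growth rate and a
    # mild static boundary irregularity (low-order radial harmonics)
    r0 = p.radius0 * (1.0 + p.heterogeneity * rng.uniform(-1, 1, size=p.n_acini))
    gr = p.growth_rate * (1.0 + p.heterogeneity * rng.uniform(-1, 1, size=p.n_acini))
    wob_amp = 0.3 * p.heterogeneity * rng.uniform(0, 1, size=(p.n_acini, 2))  # k = 2, 3
    wob_phase = rng.uniform(0, 2 * math.pi, size=(p.n_acini, 2))

    frames = np.empty((p.n_frames, H, W), dtype=np.float32)
    records = []
    crop = int(math.ceil(excl)) + 2
    for t in range(p.n_frames):
        hour = t * p.frame_interval
        plen = p.protrusion_rate * hour
        frame = np.full((H, W), 0.5, dtype=np.float32)
        for a in range(p.n_acini):
            r = r0[a] + gr[a] * hour
            cy, cx = centres[a]
            iy, ix = int(round(cy)), int(round(cx))
            y0, y1 = max(0, iy - crop), min(H, iy + crop)
            x0, x1 = max(0, ix - crop), min(W, ix + crop)
            shape = (y1 - y0, x1 - x0)
            ly, lx = cy - y0, cx - x0
            yy, xx = np.mgrid[: shape[0], : shape[1]]
            dy, dx = yy - ly, xx - lx
            theta = np.arctan2(dy, dx)
            wob = wob_amp[a, 0] * np.cos(2 * theta + wob_phase[a, 0]) + wob_amp[
                a, 1
            ] * np.cos(3 * theta + wob_phase[a, 1])
            body = dy**2 + dx**2 <= (r * (1.0 + wob)) ** 2
            if p.protrusion_rate > 0 and plen > 0:
                for ang in angles[a]:
                    tip = (ly + (r + plen) * math.sin(ang), lx + (r + plen) * math.cos(ang))
                    body |= _capsule(shape, (ly, lx), tip, p.protrusion_width)
            ring = ndi.binary_dilation(body, iterations=2) & ~body
            interior = ndi.binary_erosion(body, iterations=1)
            sub = frame[y0:y1, x0:x1]
            sub[body] = 0.25
            sub[body & ~interior] = 0.35
            sub[ring] = 0.9
            records.append(
                {
                    "acinus": a + 1,
                    "frame": t,
                    "time_h": hour,
                    "centroid_y": cy,
                    "centroid_x": cx,
                    "radius_px": r,
                    "protrusion_len_px": plen if p.protrusion_rate > 0 else 0.0,
                    "area_px2": int(body.sum()),
                    "compactness": _mask_compactness(body),
                    # even harmonics set the widest diameter of the wobbly disc
                    "feret_max_px": _acinus_truth_feret(
                        r * (1.0 + wob_amp[a, 0]),
                        plen if p.protrusion_rate > 0 else 0.0,
                        p.protrusion_width,
                        angles[a],
                    ),
                }
            )
        if p.noise_sd > 0:
            frame += rng.normal(0.0, p.noise_sd, size=frame.shape).astype(np.float32)
        frames[t] = frame

    truth = pd.DataFrame.from_records(records)
    return TimeLapse(frames, pixel_size=p.pixel_size, frame_interval=p.frame_interval), truth


# ---------------------------------------------------------------------------
# fixed 2D cell scenes (round / spread / spindle)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSceneParams:
    """Fixed-cell field with three shape archetypes and a peripheral marker.

    ``peripheral_enrichment`` is the marker mean over the 5-px periphery
    divided by the interior mean on the noiseless image.
    """

    n_cells: int = 60
    class_proportions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)  # round, spread, spindle
    peripheral_enrichment: float = 1.0
    channels: tuple[str, ...] = ("nucleus", "body", "marker")
    border_fraction: float = 0.0
    cell_radius: float = 18.0
    nucleus_radius: float = 6.0
    noise_sd: float = 0.02
    marker_positive_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.class_proportions) - 1.0) > 1e-6:
            raise ValueError("class_proportions must sum to 1 (+/- 1e-6)")
        if any(f < 0 for f in self.class_proportions):
            raise ValueError("class_proportions must be non-negative")
        if self.peripheral_enrichment < 0:
            raise ValueError("peripheral_enrichment must be >= 0")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


@dataclass
class CellScene:
    channels: dict[str, np.ndarray]
    labels: np.ndarray          # ground-truth cell label mask
    nuclei_labels: np.ndarray   # ground-truth nucleus label mask
    truth: pd.DataFrame
    params: CellSceneParams


def _apportion(n: int, proportions) -> list[int]:
    """Largest-remainder apportionment of n among classes (deterministic)."""
    raw = [n * p for p in proportions]
    counts = [int(math.floor(x)) for x in raw]
    rem = n - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (raw[i] - counts[i], -i), reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def _cell_shape(cls: str, r: float, shape, cy, cx, theta, rng) -> np.ndarray:
    """Rasterise one archetype: disc / perturbed star polygon / tapered ellipse."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    dy, dx = yy - cy, xx - cx
    u = dy * math.sin(theta) + dx * math.cos(theta)
    v = -dy * math.cos(theta) + dx * math.sin(theta)
    if cls == "round":
        return dy**2 + dx**2 <= r**2
    if cls == "spindle":
        ratio = rng.uniform(3.0, 4.0)
        a = r * math.sqrt(ratio)
        b = a / ratio
        # exponent < 2 tapers the poles relative to a true ellipse
        return (np.abs(u) / a) ** 1.6 + (np.abs(v) / b) ** 1.6 <= 1.0
    if cls == "spread":
        k = rng.integers(5, 7)
        phase = rng.uniform(0, 2 * math.pi)
        ang = np.arctan2(dy, dx)
        rad = r * (1.0 + 0.45 * np.cos(k * ang + phase))
        return dy**2 + dx**2 <= rad**2
    raise ValueError(f"unknown class {cls!r}")


def generate_cell_scene(params: CellSceneParams) -> CellScene:
    """Generate a multi-channel fixed-cell field with ground-truth labels.

    Channels: ``nucleus`` (discs), ``body`` (cell shape), ``marker`` (uniform
    interior with the 5-px periphery scaled by ``peripheral_enrichment``).
    Per-cell truth records class, realised enrichment ratio on the noiseless
    marker, marker positivity and border contact.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    counts = _apportion(p.n_cells, p.class_proportions)
    classes = sum(([c] * k for c, k in zip(SHAPE_CLASSES, counts)), [])
    rng.shuffle(classes)

    spacing = 2 * p.cell_radius * 1.6 + 8
    n_border = int(round(p.border_fraction * p.n_cells))
    centres, (H, W) = _grid_positions(p.n_cells, spacing, p.cell_radius * 1.6 + 4, rng)
    # relocate the first n_border cells onto the field border
    for i in range(n_border):
        side = i % 4
        if side == 0:
            centres[i] = (1.0, rng.uniform(spacing, W - spacing))
        elif side == 1:
            centres[i] = (H - 2.0, rng.uniform(spacing, W - spacing))
        elif side == 2:
            centres[i] = (rng.uniform(spacing, H - spacing), 1.0)
        else:
            centres[i] = (rng.uniform(spacing, H - spacing), W - 2.0)

    labels = np.zeros((H, W), dtype=np.int32)
    nuclei = np.zeros((H, W), dtype=np.int32)
    marker_truth = np.zeros((H, W), dtype=np.float64)
    records = []
    n_neg = int(round((1.0 - p.marker_positive_fraction) * p.n_cells))
    crop = int(math.ceil(p.cell_radius * 2.2)) + 2
    for i, ((cy, cx), cls) in enumerate(zip(centres, classes), start=1):
        iy, ix = int(round(cy)), int(round(cx))
        y0, y1 = max(0, iy - crop), min(H, iy + crop)
        x0, x1 = max(0, ix - crop), min(W, ix + crop)
        shape = (y1 - y0, x1 - x0)
        theta = rng.uniform(0, 2 * math.pi)
        rr = p.cell_radius * rng.uniform(0.9, 1.1)
        body = _cell_shape(cls, rr, shape, cy - y0, cx - x0, theta, rng)
        body &= labels[y0:y1, x0:x1] == 0
        nuc = _disc(shape, cy - y0, cx - x0, p.nucleus_radius) & body
        if not nuc.any():  # nucleus clipped away entirely: skip cell
            continue
        labels[y0:y1, x0:x1][body] = i
        nuclei[y0:y1, x0:x1][nuc] = i

        # marker: interior mean 100, 5-px periphery mean 100*e (noiseless)
        is_positive = not (n_border < i <= n_border + n_neg) if n_neg else True
        base = 100.0 if is_positive else 2.0
        dist_in = ndi.distance_transform_edt(body)
        periph = body & (dist_in <= 5)
        m = np.where(periph, base * p.peripheral_enrichment, np.where(body, base, 0.0))
        marker_truth[y0:y1, x0:x1] += m

        interior = body & ~periph
        realised = (
            (m[periph].mean() / m[interior].mean()) if interior.any() and periph.any() else math.nan
        )
        touches = iy - crop < 0 or ix - crop < 0 or iy + crop > H or ix + crop > W
        touches = bool(
            body[0, :].any() and y0 == 0
            or body[-1, :].any() and y1 == H
            or body[:, 0].any() and x0 == 0
            or body[:, -1].any() and x1 == W
        )
        records.append(
            {
                "cell": i,
                "shape_class": cls,
                "centroid_y": cy,
                "centroid_x": cx,
                "area_px2": int(body.sum()),
                "enrichment_true": p.peripheral_enrichment,
                "enrichment_realised": realised,
                "marker_positive": is_positive,
                "touches_border": touches,
            }
        )

    nucleus_img = np.where(nuclei > 0, 200.0, 0.0)
    body_img = np.where(labels > 0, 120.0, 0.0)
    channels: dict[str, np.ndarray] = {}
    for name, img in (("nucleus", nucleus_img), ("body", body_img), ("marker", marker_truth)):
        if name in p.channels:
            out = img.astype(np.float64)
            if p.noise_sd > 0:
                out = out + rng.normal(0.0, p.noise_sd * 100.0, size=img.shape)
            channels[name] = out
    truth = pd.DataFrame.from_records(records)
    return CellScene(channels=channels, labels=labels, nuclei_labels=nuclei, truth=truth, params=p)


# ---------------------------------------------------------------------------
# two-channel spot scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpotSceneParams:
    """Two-channel punctate scene with a known green-in-red overlap fraction.

    ``true_overlap_fraction`` of the green spots are placed exactly on red
    spot centres; the remainder are kept at least one spot diameter away from
    every red spot, so the realised per-cell overlap is recorded exactly.
    """

    n_green: int = 20
    n_red: int = 20
    spot_radius: float = 3.0
    true_overlap_fraction: float = 0.5
    cell_layout: tuple[int, int] = (2, 3)   # rows x cols of cells per field
    cell_radius: float = 42.0
    spot_amplitude: float = 150.0
    background: float = 10.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.true_overlap_fraction <= 1.0):
            raise ValueError("true_overlap_fraction must be in [0, 1]")
        if self.n_green < 1 or self.n_red < 1:
            raise ValueError("need at least one spot per channel")


@dataclass
class SpotScene:
    green: np.ndarray
    red: np.ndarray
    cells: np.ndarray            # cell label mask
    green_spots: np.ndarray      # boolean truth masks
    red_spots: np.ndarray
    truth: pd.DataFrame          # per-cell realised overlap %
    params: SpotSceneParams


def generate_spot_scene(params: SpotSceneParams) -> SpotScene:
    """Generate green/red punctate channels over a grid of round cells."""
    p = params
    rng = np.random.default_rng(p.seed)
    nrow, ncol = p.cell_layout
    pitch = 2 * p.cell_radius + 12
    H, W = int(nrow * pitch), int(ncol * pitch)
    cells = np.zeros((H, W), dtype=np.int32)
    green_mask = np.zeros((H, W), dtype=bool)
    red_mask = np.zeros((H, W), dtype=bool)
    records = []

    n_coincident = int(round(p.true_overlap_fraction * p.n_green))
    min_sep = 2 * p.spot_radius + 2.0

    cid = 0
    for i in range(nrow):
        for j in range(ncol):
            cid += 1
            cy, cx = (i + 0.5) * pitch, (j + 0.5) * pitch
            cell = _disc((H, W), cy, cx, p.cell_radius)
            cells[cell] = cid

            def _sample_point():
                ang = rng.uniform(0, 2 * math.pi)
                rad = p.cell_radius * 0.85 * math.sqrt(rng.uniform())
                return cy + rad * math.sin(ang), cx + rad * math.cos(ang)

            red_pts = []
            for _ in range(p.n_red):
                for _try in range(500):
                    y, x = _sample_point()
                    if all((y - ry) ** 2 + (x - rx) ** 2 >= min_sep**2 for ry, rx in red_pts):
                        red_pts.append((y, x))
                        break
                else:
                    raise ValueError("cannot place red spots without overlap; reduce n_red")
            order = rng.permutation(p.n_red)
            green_pts = [red_pts[order[k % p.n_red]] for k in range(n_coincident)]
            for _ in range(p.n_green - n_coincident):
                for _try in range(500):
                    y, x = _sample_point()
                    if all(
                        (y - ry) ** 2 + (x - rx) ** 2 >= min_sep**2 for ry, rx in red_pts
                    ) and all(
                        (y - gy) ** 2 + (x - gx) ** 2 >= min_sep**2 for gy, gx in green_pts
                    ):
                        green_pts.append((y, x))
                        break
                else:
                    raise ValueError("cannot place disjoint green spots; reduce counts")

            for y, x in red_pts:
                red_mask |= _disc((H, W), y, x, p.spot_radius)
            g_cell = np.zeros((H, W), dtype=bool)
            for y, x in green_pts:
                g_cell |= _disc((H, W), y, x, p.spot_radius)
            green_mask |= g_cell

            g_area = int(g_cell.sum())
            ov = int((g_cell & red_mask).sum())
            records.append(
                {
                    "cell": cid,
                    "green_spot_area_px2": g_area,
                    "overlap_area_px2": ov,
                    "percent_overlap": 100.0 * ov / g_area if g_area else math.nan,
                    "n_green": p.n_green,
                    "n_red": p.n_red,
                }
            )

    def _render(mask):
        img = np.full((H, W), p.background, dtype=np.float64)
        img[mask] += p.spot_amplitude
        img = ndi.gaussian_filter(img, 0.8)
        if p.noise_sd > 0:
            img += rng.normal(0.0, p.noise_sd, size=img.shape)
        return img

    return SpotScene(
        green=_render(green_mask),
        red=_render(red_mask),
        cells=cells,
        green_spots=green_mask,
        red_spots=red_mask,
        truth=pd.DataFrame.from_records(records),
        params=p,
    )


# ---------------------------------------------------------------------------
# wound-closure mask series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WoundSimParams:
    """Wounded-monolayer confluence-mask series.

    A vertical cell-free stripe of width ``wound_width0`` closes from both
    edges at ``closure_rate`` px/h; ``invasive=True`` adds protrusive fingers
    (rows that close faster) at the wound edge.
    """

    field_size: tuple[int, int] = (256, 256)
    wound_width0: float = 80.0
    closure_rate: float = 2.0     # px/h advance of each wound edge
    invasive: bool = False
    n_frames: int = 24
    frame_interval: float = 1.0   # h
    seed: int = 0

    def __post_init__(self):
        if self.wound_width0 >= self.field_size[1]:
            raise ValueError("wound must lie strictly inside the field")
        if self.wound_width0 <= 0 or self.n_frames < 1:
            raise ValueError("invalid wound geometry")


def generate_wound_series(params: WoundSimParams) -> tuple[TimeLapse, pd.DataFrame]:
    """Boolean confluence masks (True = cell-covered) for a closing wound."""
    p = params
    rng = np.random.default_rng(p.seed)
    H, W = p.field_size
    cx = W / 2.0
    rows = np.arange(H)
    if p.invasive:
        # smooth random per-row extra closure speed: protrusive fingering
        boost = rng.uniform(0.0, 1.0, size=H)
        boost = ndi.gaussian_filter1d(boost, 6.0)
        boost = 1.5 * (boost - boost.min()) / max(float(np.ptp(boost)), 1e-12)
    else:
        boost = np.zeros(H)

    frames = np.empty((p.n_frames, H, W), dtype=bool)
    rec = []
    xs = np.arange(W)
    for t in range(p.n_frames):
        hour = t * p.frame_interval
        half = np.maximum(0.0, p.wound_width0 / 2.0 - (p.closure_rate + boost) * hour)
        mask = np.abs(xs[None, :] - cx) >= half[:, None]
        frames[t] = mask
        rec.append({"frame": t, "time_h": hour, "wound_area_px2": int((~mask).sum())})
    truth = pd.DataFrame.from_records(rec)
    return TimeLapse(frames, frame_interval=p.frame_interval), truth


# ---------------------------------------------------------------------------
# receptor-trafficking series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraffickingSimParams:
    """Marker redistribution from a membrane band to a juxtanuclear ring.

    ``fractions`` maps each timepoint (hours) to the (membrane, cytoplasm,
    juxtanuclear) intensity simplex; defaults emulate surface labelling at
    t=0 followed by internalisation over 10 and 30 minutes.
    """

    n_cells: int = 40
    timepoints: tuple[float, ...] = (0.0, 10 / 60, 30 / 60)
    membrane_fraction: tuple[float, ...] = (0.90, 0.45, 0.15)
    cytoplasm_fraction: tuple[float, ...] = (0.08, 0.25, 0.20)
    juxtanuclear_fraction: tuple[float, ...] = (0.02, 0.30, 0.65)
    total_intensity: float = 1e5
    cell_radius: float = 20.0
    nucleus_radius: float = 7.0
    band_px: int = 5
    jn_radius: int = 5
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        n = len(self.timepoints)
        if not (len(self.membrane_fraction) == len(self.cytoplasm_fraction) == len(self.juxtanuclear_fraction) == n):
            raise ValueError("one fraction triple per timepoint required")
        for m, c, j in zip(self.membrane_fraction, self.cytoplasm_fraction, self.juxtanuclear_fraction):
            if min(m, c, j) < 0 or abs(m + c + j - 1.0) > 1e-6:
                raise ValueError("fractions must be a simplex (sum to 1) at each timepoint")
        if n < 1:
            raise ValueError("need at least one timepoint")


@dataclass
class TraffickingSeries:
    """One rendered field per timepoint plus per-cell ground-truth regions."""

    times: list[float]
    images: list[np.ndarray]
    regions: list[list[RegionMasks]]   # per timepoint, per cell
    truth: pd.DataFrame

    def frames(self):
        for t, img, regs in zip(self.times, self.images, self.regions):
            yield t, img, regs


def generate_trafficking_series(params: TraffickingSimParams) -> TraffickingSeries:
    """Render per-timepoint fields in which marker intensity redistributes."""
    p = params
    rng = np.random.default_rng(p.seed)
    spacing = 2 * p.cell_radius + 10
    centres, (H, W) = _grid_positions(p.n_cells, spacing, p.cell_radius + 5, rng)

    # static geometry shared by all timepoints
    geom = []
    for cy, cx in centres:
        cell = _disc((H, W), cy, cx, p.cell_radius)
        nuc = _disc((H, W), cy, cx, p.nucleus_radius)
        dist_in = ndi.distance_transform_edt(cell)
        membrane = cell & (dist_in <= p.band_px) & ~nuc
        jn = _disc((H, W), cy, cx, p.nucleus_radius + p.jn_radius) & ~nuc & cell
        cyto = cell & ~membrane & ~nuc
        geom.append(
            RegionMasks(cell=cell, nucleus=nuc, peripheral=membrane, cytoplasm=cyto, juxtanuclear=jn)
        )
    # deposition targets: the cytoplasm share goes outside the juxtanuclear
    # ring so the three deposited compartments are pairwise disjoint
    deposit = [
        (rm.peripheral, rm.cytoplasm & ~rm.juxtanuclear, rm.juxtanuclear) for rm in geom
    ]

    times, images, regions, rec = [], [], [], []
    for k, t in enumerate(p.timepoints):
        fr = (p.membrane_fraction[k], p.cytoplasm_fraction[k], p.juxtanuclear_fraction[k])
        img = np.zeros((H, W), dtype=np.float64)
        for ci, rm in enumerate(geom, start=1):
            for f, region in zip(fr, deposit[ci - 1]):
                n_px = int(region.sum())
                if n_px and f > 0:
                    img[region] += f * p.total_intensity / n_px
            rec.append(
                {
                    "time_h": t,
                    "cell": ci,
                    "membrane_fraction": fr[0],
                    "cytoplasm_fraction": fr[1],
                    "juxtanuclear_fraction": fr[2],
                    "total_intensity": p.total_intensity,
                }
            )
        if p.noise_sd > 0:
            img = img + rng.normal(0.0, p.noise_sd, size=img.shape)
        times.append(t)
        images.append(img)
        regions.append(geom)
    return TraffickingSeries(times=times, images=images, regions=regions, truth=pd.DataFrame.from_records(rec))
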