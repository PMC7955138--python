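"""End-to-end convenience pipelines composing the per-stage operations.

These are thin orchestration layers: simulate (or accept) a time-lapse,
segment every frame, reduce to 12-h blocks, and normalise/test across
conditions — the growth-versus-invasion readout in one call.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import segmentation, stats_report, timecourse
from .containers import TimeLapse
from .synthetic import AcinusSimParams, generate_acinus_timelapse

__all__ = ["analyse_acinus_timelapse", "growth_invasion_screen"]


def analyse_acinus_timelapse(
    tl: TimeLapse,
    cfg: segmentation.SegConfig | None = None,
    block_hours: float = 12.0,
    well: str | None = None,
) -> pd.DataFrame:
    """Segment every frame and reduce to per-object 12-h block metrics."""
    masks = [segmentation.segment_acini(f, cfg) for f in tl.frames]
    table, _ = timecourse.block_metrics(
        masks,
        block_hours=block_hours,
        frame_interval=tl.frame_interval,
        pixel_size=tl.pixel_size,
        well=well,
    )
    return table


def growth_invasion_screen(
    conditions: dict[str, AcinusSimParams],
    control: str,
    block_hours: float = 12.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate, measure and normalise an acinus cohort per condition.

    Returns ``(blocks, normed, summary)``: the pooled per-object block
    table; the final-block area/compactness values Z-scored to the control;
    and a per-condition summary with one-way ANOVA p-values against the
    control for both metrics.
    """
    if control not in conditions:
        raise ValueError("control condition missing")
    blocks = []
    for name, params in conditions.items():
        tl, _ = generate_acinus_timelapse(params)
        t = analyse_acinus_timelapse(tl, block_hours=block_hours, well=name)
        t["condition"] = name
        t["experiment"] = "sim"
        blocks.append(t)
    blocks = pd.concat(blocks, ignore_index=True)

    last_block = blocks[~blocks["partial"]]["block_index"].max()
    final = blocks[blocks["block_index"] == last_block].copy()

    normed = []
    for metric in ("area_px2", "compactness"):
        t = final.rename(columns={metric: "value"})[
            ["experiment", "condition", "track", "value"]
        ].copy()
        t = stats_report.zscore_to_control(t, control)
        t["metric"] = metric
        normed.append(t)
    normed = pd.concat(normed, ignore_index=True)

    rows = []
    for metric in ("area_px2", "compactness"):
        sub = normed[normed["metric"] == metric]
        ctrl_vals = sub.loc[sub["condition"] == control, "value"].to_numpy()
        for cond in conditions:
            vals = sub.loc[sub["condition"] == cond, "value"].to_numpy()
            if cond == control:
                stat = p = np.nan
            else:
                stat, p = stats_report.group_tests([ctrl_vals, vals], "anova")
            rows.append(
                {
                    "condition": cond,
                    "metric": metric,
                    "zscore": sub.loc[sub["condition"] == cond, "zscore"].mean(),
                    "p_value": p,
                    "f_statistic": stat,
                }
            )
    return blocks, normed, pd.DataFrame(rows)
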