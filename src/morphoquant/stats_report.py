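"""Normalisation and reporting: Z-score to control, log2 fold change,
one-way ANOVA / Welch tests, and heatmap export.

High-content experiments are pooled across independent replicates by first
normalising each measurement to the control condition *within its own
experiment* — Z = (x - mean_control) / sd_control with the sample (n-1)
standard deviation — then collating. This removes per-batch baseline shifts
before conditions are compared.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "zscore_to_control",
    "log2_fold_change",
    "group_tests",
    "benjamini_hochberg",
    "heatmap_export",
]


def _check_columns(df: pd.DataFrame, cols) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns {missing}")


def zscore_to_control(
    table: pd.DataFrame,
    control: str,
    condition_col: str = "condition",
    value_col: str = "value",
    experiment_col: str = "experiment",
    scope: str = "experiment",
) -> pd.DataFrame:
    """Z-score every value against the control condition.

    ``scope='experiment'`` (default) computes control mean/sd separately in
    each experiment and pools afterwards; ``scope='global'`` uses one pooled
    control. Raises if the control is absent from any experiment in scope or
    has zero standard deviation.
    """
    _check_columns(table, [condition_col, value_col])
    out = table.copy()
    if scope == "experiment":
        _check_columns(table, [experiment_col])
        groups = out.groupby(experiment_col, sort=False)
    elif scope == "global":
        groups = [(None, out)]
    else:
        raise ValueError("scope must be 'experiment' or 'global'")

    z = pd.Series(index=out.index, dtype=float)
    for key, grp in groups:
        ctrl = grp.loc[grp[condition_col] == control, value_col]
        if ctrl.empty:
            raise ValueError(f"control condition {control!r} missing in experiment {key!r}")
        mu = ctrl.mean()
        sd = ctrl.std(ddof=1)
        if not sd or math.isnan(sd):
            raise ValueError(f"control sd is zero/undefined in experiment {key!r}")
        z.loc[grp.index] = (grp[value_col] - mu) / sd
    out["zscore"] = z
    return out


def log2_fold_change(
    table: pd.DataFrame,
    control: str,
    condition_col: str = "condition",
    value_col: str = "value",
    experiment_col: str = "experiment",
    scope: str = "experiment",
) -> pd.DataFrame:
    """Per-row log2(value / control mean), control mean within scope.

    A non-positive control mean makes the fold change undefined and raises.
    """
    _check_columns(table, [condition_col, value_col])
    out = table.copy()
    if scope == "experiment":
        _check_columns(table, [experiment_col])
        groups = out.groupby(experiment_col, sort=False)
    else:
        groups = [(None, out)]
    fc = pd.Series(index=out.index, dtype=float)
    for key, grp in groups:
        ctrl = grp.loc[grp[condition_col] == control, value_col]
        if ctrl.empty:
            raise ValueError(f"control condition {control!r} missing in experiment {key!r}")
        mu = ctrl.mean()
        if mu <= 0:
            raise ValueError("log2 fold change undefined for non-positive control mean")
        fc.loc[grp.index] = np.log2(grp[value_col] / mu)
    out["log2fc"] = fc
    return out


def group_tests(groups: list, method: str = "anova") -> tuple[float, float]:
    """One-way ANOVA F-test or Welch's two-tailed unequal-variance t-test.

    Returns ``(statistic, p_value)``. ANOVA needs >= 2 groups, Welch exactly
    2; every group needs n >= 2.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in groups):
        raise ValueError("every group needs at least 2 observations")
    if method == "anova":
        if len(groups) < 2:
            raise ValueError("ANOVA needs at least two groups")
        res = sps.f_oneway(*groups)
    elif method == "welch":
        if len(groups) != 2:
            raise ValueError("Welch test needs exactly two groups")
        res = sps.ttest_ind(groups[0], groups[1], equal_var=False)
    else:
        raise ValueError("method must be 'anova' or 'welch'")
    return float(res.statistic), float(res.pvalue)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH-adjusted p-values (optional; raw p-values are reported by default)."""
    p = np.asarray(p_values, dtype=float)
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.clip(adj, 0, 1)
    return out


def heatmap_export(
    table: pd.DataFrame,
    png_path,
    csv_path=None,
    condition_col: str = "condition",
    metric_col: str = "metric",
    value_col: str = "zscore",
    p_col: str | None = "p_value",
    vmin: float = -3.0,
    vmax: float = 3.0,
) -> pd.DataFrame:
    """Export a condition x metric Z-score heatmap with a greyscale p strip.

    The rendered values are clipped to [vmin, vmax]; the companion CSV
    (always written, deterministic byte-for-byte for identical input) keeps
    the unclipped values plus a ``clipped`` marker column.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    _check_columns(table, [condition_col, metric_col, value_col])
    pivot = table.pivot_table(index=condition_col, columns=metric_col, values=value_col,
                              aggfunc="mean", sort=False)
    clipped = pivot.clip(vmin, vmax)
    has_p = p_col is not None and p_col in table.columns
    ncols = 2 if has_p else 1
    fig, axes = plt.subplots(
        1, ncols, figsize=(2 + 0.8 * (pivot.shape[1] + 1), 1 + 0.5 * pivot.shape[0]),
        squeeze=False,
    )
    ax = axes[0, 0]
    im = ax.imshow(clipped.to_numpy(float), cmap="RdBu_r", vmin=vmin, vmax=vmax, aspect="auto")
    ax.set_xticks(range(pivot.shape[1]), pivot.columns, rotation=45, ha="right")
    ax.set_yticks(range(pivot.shape[0]), pivot.index)
    fig.colorbar(im, ax=ax, label=value_col)
    if has_p:
        pv = table.pivot_table(index=condition_col, columns=metric_col, values=p_col,
                               aggfunc="mean", sort=False)
        ax2 = axes[0, 1]
        im2 = ax2.imshow(pv.to_numpy(float), cmap="Greys_r", vmin=0.0, vmax=0.1, aspect="auto")
        ax2.set_xticks(range(pv.shape[1]), pv.columns, rotation=45, ha="right")
        ax2.set_yticks([])
        fig.colorbar(im2, ax=ax2, label="p value")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)

    long = clipped.reset_index().melt(id_vars=condition_col, var_name=metric_col,
                                      value_name=value_col)
    raw = pivot.reset_index().melt(id_vars=condition_col, var_name=metric_col,
                                   value_name="raw_" + value_col)
    long = long.merge(raw, on=[condition_col, metric_col])
    long["clipped"] = long[value_col] != long["raw_" + value_col]
    if csv_path is None:
        csv_path = str(png_path) + ".csv"
    long.sort_values([condition_col, metric_col], kind="stable").to_csv(csv_path, index=False)
    return long
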