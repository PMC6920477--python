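"""Trend heatmaps for significant time-course gene sets.

Rows are per-set trend clusters (median standardized expression over
subjects, zeroed at T1), columns are timepoints; a red-up / blue-down
diverging palette is centred on zero so upregulation relative to baseline
reads red.  Rows are ordered by hierarchical clustering of the trend
vectors.  Output is deterministic for identical inputs.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage

from .tcgsa import TrajectoryResult


def trend_table(
    results: "list[TrajectoryResult]",
    alpha: float = 0.05,
    exclude_sets: "list[str] | None" = None,
) -> pd.DataFrame:
    """Stack the trend rows of significant converged sets into one table
    (rows labelled ``SET/trend_k``); ``exclude_sets`` removes sets flagged
    for non-homogeneous expression from the visualisation."""
    drop = set(exclude_sets or [])
    rows, labels = [], []
    for r in results:
        if not r.converged or not np.isfinite(r.q) or r.q >= alpha:
            continue
        if r.set_name in drop or r.trends is None:
            continue
        for trend_name, row in r.trends.values.iterrows():
            rows.append(row.to_numpy())
            labels.append(f"{r.set_name}/{trend_name}")
    if not rows:
        return pd.DataFrame(columns=["T1", "T2", "T3"])
    return pd.DataFrame(np.vstack(rows), index=labels, columns=["T1", "T2", "T3"])


def render_trend_heatmap(
    results: "list[TrajectoryResult]",
    out_path: str | Path,
    alpha: float = 0.05,
    exclude_sets: "list[str] | None" = None,
    title: str = "",
) -> Path:
    """Write a PNG heatmap of significant trend dynamics.

    With nothing significant an empty-state placeholder is written and a
    warning issued (the file still exists, so downstream bookkeeping holds).
    """
    out_path = Path(out_path)
    table = trend_table(results, alpha=alpha, exclude_sets=exclude_sets)
    if table.empty:
        warnings.warn(f"no significant converged sets; writing placeholder to {out_path}")
        fig, ax = plt.subplots(figsize=(4, 2))
        ax.text(0.5, 0.5, "no significant gene sets", ha="center", va="center")
        ax.set_axis_off()
        fig.savefig(out_path, dpi=100, metadata={"Software": "sdtx"})
        plt.close(fig)
        return out_path
    if len(table) > 2:
        order = leaves_list(linkage(table.to_numpy(), method="complete"))
        table = table.iloc[order]
    vmax = max(float(np.abs(table.to_numpy()).max()), 1e-6)
    fig_h = max(2.0, 0.22 * len(table) + 1.2)
    fig, ax = plt.subplots(figsize=(6, fig_h))
    im = ax.imshow(
        table.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-vmax, vmax=vmax
    )
    ax.set_xticks(range(3), table.columns)
    ax.set_yticks(range(len(table)), table.index, fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, label="median standardized expression (vs T1)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=100, metadata={"Software": "sdtx"})
    plt.close(fig)
    return out_path
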