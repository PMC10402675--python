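"""Rendering of classified zone grids and QA scatter plots."""
from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd
from matplotlib.colors import ListedColormap
from matplotlib.patches import Patch

from .zones import ZONE_NAMES, ZoneGrid

__all__ = ["render_zone_grid", "scatter_qa"]

# fixed zone -> color mapping, ordered by ZoneLabel
ZONE_COLORS = (
    "#ffffff",  # open
    "#ffd54f",  # calibration
    "#64b5f6",  # tip
    "#455a64",  # body
    "#8e24aa",  # paired
    "#e53935",  # exposed
    "#43a047",  # neglected
)


def render_zone_grid(grid: ZoneGrid, path: str | Path, title: str = "") -> Path:
    """Write a PNG of the zone map with the fixed legend."""
    path = Path(path)
    fig, ax = plt.subplots(figsize=(7, 6))
    extent = (
        grid.x_origin,
        grid.x_origin + grid.n_x * grid.spacing,
        grid.y_origin,
        grid.y_origin + grid.n_y * grid.spacing,
    )
    ax.imshow(
        grid.labels,
        origin="lower",
        extent=extent,
        cmap=ListedColormap(ZONE_COLORS),
        vmin=-0.5,
        vmax=6.5,
        interpolation="nearest",
    )
    ax.set_xlabel("x (cm, leaf travel)")
    ax.set_ylabel("y (cm)")
    if title:
        ax.set_title(title)
    ax.legend(
        handles=[
            Patch(facecolor=c, edgecolor="k", label=n)
            for c, n in zip(ZONE_COLORS, ZONE_NAMES)
        ],
        loc="center left",
        bbox_to_anchor=(1.02, 0.5),
        fontsize=8,
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def scatter_qa(
    plan_table: pd.DataFrame,
    dqa_df: pd.DataFrame,
    zone: str,
    qa_metric: str,
    path: str | Path,
) -> Path:
    """Scatter a QA quantity against one zone's average GPF."""
    path = Path(path)
    merged = plan_table.merge(dqa_df, on="plan_id")
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(merged[zone], merged[qa_metric], s=18)
    ax.set_xlabel(f"average {zone} GPF")
    ax.set_ylabel(qa_metric.replace("_", " "))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
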