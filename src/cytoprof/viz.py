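"""Visualization contracts as pure data transforms, plus optional rendering.

Three views: (1) blend coloring of a SPADE tree by the sign of each node's
fold change and the raw-p significance of its test; (2) Radviz, which pins
each channel to a point on the unit circle and places every cell at the
centroid of the anchors weighted by its normalized intensities; (3) fan
charts — per-condition centile tables drawn as stacked bands centered on
the median. The data transforms are the tested surface; the matplotlib
renderers are thin conveniences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BlendColor",
    "RadvizLayout",
    "spade_blend_coloring",
    "radviz_projection",
    "fan_chart_centiles",
    "plot_radviz",
    "plot_fan_chart",
]


@dataclass
class RadvizLayout:
    anchors: pd.DataFrame  # channel -> (x, y) on the unit circle
    points: np.ndarray  # cells x 2


BlendColor = pd.DataFrame  # node -> (direction, emphasis); alias for clarity


def spade_blend_coloring(diff: pd.DataFrame, alpha: float = 0.05,
                         nodes=None) -> pd.DataFrame:
    """Map per-node differential results to blend color classes.

    Direction follows the sign of the fold change ("decrease"/"increase"),
    emphasis is "significant" when the *raw* p-value is below ``alpha`` —
    the tree is an exploratory view, so no multiplicity correction here.
    Nodes in ``nodes`` that are absent from ``diff`` come back as
    ("excluded", "excluded"), the grayed-out state.
    """
    out = {}
    for row in diff.itertuples(index=False):
        direction = "decrease" if row.fold_change < 0 else "increase"
        emphasis = "significant" if row.raw_p < alpha else "nonsignificant"
        out[row.unit] = (direction, emphasis)
    if nodes is not None:
        for node in nodes:
            out.setdefault(node, ("excluded", "excluded"))
    df = pd.DataFrame.from_dict(out, orient="index",
                                columns=["direction", "emphasis"])
    df.index.name = "unit"
    return df.sort_index()


def radviz_projection(cells: np.ndarray, channels: list[str]) -> RadvizLayout:
    """Radviz: anchors equally spaced on the unit circle, cells at their
    normalized-intensity-weighted centroid.

    Intensities are min-max normalized to [0, 1] per channel across the
    projected cells, so every point is a convex combination of the anchors
    (all-zero cells sit at the origin). The anchor order is the given
    channel order.
    """
    cells = np.asarray(cells, dtype=float)
    k = len(channels)
    if k < 3:
        raise ValueError("Radviz needs at least 3 channels")
    if cells.ndim != 2 or cells.shape[1] != k:
        raise ValueError("cells must be n x len(channels)")
    angles = 2 * np.pi * np.arange(k) / k
    anchors = np.column_stack([np.cos(angles), np.sin(angles)])

    lo = cells.min(axis=0)
    rng_ = cells.max(axis=0) - lo
    rng_[rng_ == 0] = 1.0  # constant channel -> normalized to 0
    u = (cells - lo) / rng_
    totals = u.sum(axis=1, keepdims=True)
    safe = np.where(totals == 0, 1.0, totals)
    pts = (u @ anchors) / safe
    pts[totals.ravel() == 0] = 0.0
    return RadvizLayout(
        anchors=pd.DataFrame(anchors, index=channels, columns=["x", "y"]),
        points=pts,
    )


def fan_chart_centiles(
    values_by_condition: dict[str, np.ndarray],
    centile_grid=tuple(range(5, 100, 5)),
) -> pd.DataFrame:
    """Per-condition centile table for fan-chart rendering.

    Rows are conditions, columns the centile grid (default 5..95 by 5);
    values are monotone non-decreasing along each row and the 50th centile
    column is the condition median. Empty conditions are excluded.
    """
    grid = sorted(centile_grid)
    rows = {}
    for cond, vals in values_by_condition.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            continue
        rows[cond] = np.percentile(v, grid)
    if not rows:
        raise ValueError("no non-empty conditions")
    return pd.DataFrame.from_dict(rows, orient="index", columns=grid)


# ---------------------------------------------------------------------------
# optional matplotlib renderers (not part of the tested surface)
# ---------------------------------------------------------------------------

def plot_radviz(layout: RadvizLayout, ax=None, **scatter_kw):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    circle = plt.Circle((0, 0), 1.0, fill=False, color="0.7")
    ax.add_patch(circle)
    ax.scatter(layout.points[:, 0], layout.points[:, 1], s=4, **scatter_kw)
    for ch, row in layout.anchors.iterrows():
        ax.annotate(ch, (row.x, row.y), ha="center", va="center")
    ax.set_aspect("equal")
    ax.set_axis_off()
    return ax


def plot_fan_chart(centiles: pd.DataFrame, condition: str, ax=None):
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    row = centiles.loc[condition]
    grid = np.asarray(row.index, dtype=float)
    med = np.interp(50, grid, row.values)
    for lo, hi in zip(grid[:-1], grid[1:]):
        depth = 1 - abs((lo + hi) / 2 - 50) / 50
        ax.fill_between([0, 1], row[lo], row[hi], alpha=0.2 + 0.6 * depth,
                        color="C0", linewidth=0)
    ax.axhline(med, color="k", lw=1)
    ax.set_xticks([])
    ax.set_title(condition)
    return ax
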