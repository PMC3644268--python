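"""The net heat plot: clustered Q-difference colors with hat-matrix squares.

Cell (d', d) is colored by Q^diff_{d',d} on a symmetric diverging scale —
warm colors for positive values (detaching d reduces d''s inconsistency),
blue for negative — saturating at a configurable cap (default 8).  A
centered gray square with area proportional to |H_{d',d}| overlays each
cell, showing how strongly the direct estimate of d drives the network
estimate of d'.  Rows and columns are reordered by complete-linkage
clustering of the Q-difference matrix so that interrelated residuals form
visible blocks ("hot spots").
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd
from matplotlib import pyplot as plt
from matplotlib.colors import BoundaryNorm, LinearSegmentedColormap
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .detach import QDiffMatrix

__all__ = ["NetHeatLayout", "cluster_order", "build_layout", "render_netheat"]

DEFAULT_COLOR_CAP = 8.0
_N_BINS = 13

# blue (negative) -> white (zero) -> yellow/orange/red (positive)
_CMAP = LinearSegmentedColormap.from_list(
    "netheat",
    ["#053061", "#2166ac", "#4393c3", "#92c5de", "#d1e5f0", "#ffffff",
     "#ffffbf", "#fee090", "#fdae61", "#f46d43", "#d73027", "#a50026"],
)


@dataclass(frozen=True)
class NetHeatLayout:
    """Everything needed to draw the plot, already reordered."""

    order: tuple[str, ...]            # design order (columns)
    row_order: tuple[str, ...]        # design-contrast rows, same design order
    qdiff: pd.DataFrame               # rows=row_order, cols=order
    hat_areas: pd.DataFrame           # |H| restricted/reordered like qdiff
    color_cap: float = DEFAULT_COLOR_CAP

    def __post_init__(self):
        if self.color_cap <= 0:
            raise ValueError("color_cap must be positive")


def cluster_order(qdiff: QDiffMatrix | pd.DataFrame) -> list[str]:
    """Leaf order from complete-linkage clustering of the design-level matrix.

    The distance between designs i and j is the sum of the absolute
    row differences and the absolute column differences of the
    design-level Q-difference matrix.  Labels are pre-sorted so ties
    break deterministically.
    """
    Q = qdiff.design_level() if isinstance(qdiff, QDiffMatrix) else qdiff
    if Q.shape[0] != Q.shape[1] or list(Q.index) != list(Q.columns):
        raise ValueError("cluster_order needs a square matrix with matching labels")
    labels = sorted(Q.index)
    if len(labels) < 2:
        return labels
    Q = Q.loc[labels, labels].to_numpy()
    n = len(labels)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(Q[i] - Q[j]).sum() + np.abs(Q[:, i] - Q[:, j]).sum()
            dist[i, j] = dist[j, i] = d
    if not dist.any():  # nothing to distinguish: keep the label-sorted order
        return labels
    link = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return [labels[i] for i in hierarchy.leaves_list(link)]


def build_layout(
    qdiff: QDiffMatrix,
    hat: pd.DataFrame,
    color_cap: float = DEFAULT_COLOR_CAP,
    cluster: bool = True,
) -> NetHeatLayout:
    """Restrict the hat matrix to the plotted designs and order everything.

    ``hat`` is the full design-contrast hat matrix (see
    :func:`nmadiag.gls.hat_contributions`); rows and columns belonging to
    non-detachable designs are dropped, per the exclusion rule.
    """
    order = cluster_order(qdiff) if cluster else list(qdiff.col_labels)
    row_order = [lbl for d in order for lbl in qdiff.design_rows[d]]
    values = qdiff.values.loc[row_order, order]
    # hat columns are design-contrast labels; aggregate multi-arm columns
    # of one design by summing the coefficients of its contrasts.
    hat_cols = {}
    for d in order:
        cols = qdiff.design_rows[d]
        hat_cols[d] = hat.loc[row_order, cols].sum(axis=1)
    areas = pd.DataFrame(hat_cols)[order].abs().clip(upper=1.0)
    return NetHeatLayout(
        order=tuple(order),
        row_order=tuple(row_order),
        qdiff=values,
        hat_areas=areas,
        color_cap=float(color_cap),
    )


def render_netheat(layout: NetHeatLayout, out, format: str | None = None):
    """Render the net heat plot to ``out`` (path); returns the path.

    Output is a pure function of the layout: SVG output is byte-identical
    across runs for identical layouts.
    """
    cap = layout.color_cap
    bounds = np.linspace(-cap, cap, _N_BINS + 1)
    norm = BoundaryNorm(bounds, _CMAP.N, clip=True)

    q = layout.qdiff.to_numpy()
    areas = layout.hat_areas.to_numpy()
    n_rows, n_cols = q.shape

    with matplotlib.rc_context({"svg.hashsalt": "nmadiag"}):
        fig, ax = plt.subplots(
            figsize=(max(4.0, 0.45 * n_cols + 2.2), max(3.5, 0.45 * n_rows + 1.8))
        )
        mesh = ax.pcolormesh(
            np.arange(n_cols + 1),
            np.arange(n_rows + 1),
            q,
            cmap=_CMAP,
            norm=norm,
            edgecolors="lightgray",
            linewidth=0.4,
        )
        for i in range(n_rows):
            for j in range(n_cols):
                side = float(np.sqrt(areas[i, j]))  # area proportional to |H|
                if side <= 0:
                    continue
                ax.add_patch(
                    plt.Rectangle(
                        (j + (1 - side) / 2, i + (1 - side) / 2),
                        side,
                        side,
                        facecolor="0.45",
                        edgecolor="none",
                        alpha=0.75,
                    )
                )
        ax.set_xticks(np.arange(n_cols) + 0.5, layout.order, rotation=90, fontsize=8)
        ax.set_yticks(np.arange(n_rows) + 0.5, layout.row_order, fontsize=8)
        ax.invert_yaxis()
        ax.set_xlabel("detached design d")
        ax.set_ylabel("design-contrast d'")
        cbar = fig.colorbar(mesh, ax=ax, ticks=bounds[::2])
        cbar.set_label("Q$^{diff}$ (warm: inconsistency reduced; blue: increased)")
        fig.tight_layout()
        fig.savefig(out, format=format, metadata=_metadata_for(format, out))
        plt.close(fig)
    return out


def _metadata_for(format, out):
    fmt = (format or str(out).rsplit(".", 1)[-1]).lower()
    if fmt == "svg":
        return {"Date": None}  # reproducible output
    if fmt == "png":
        return {"Software": None}
    return None
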