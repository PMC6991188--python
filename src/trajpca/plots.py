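"""Projection plots of reduced paths.

Paths are drawn as color-mapped polylines running from the start (dark) to
the end (light) of the path, viridis by default.  These figures are
illustrative output; the numerical content lives in the scores tables.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from matplotlib.collections import LineCollection  # noqa: E402
from mpl_toolkits.mplot3d.art3d import Line3DCollection  # noqa: E402
import numpy as np  # noqa: E402

from .model import ReducedPath  # noqa: E402

__all__ = ["plot_path_2d", "plot_path_3d"]


def _segments(scores: np.ndarray) -> np.ndarray:
    pts = scores[:, None, :]
    return np.concatenate([pts[:-1], pts[1:]], axis=1)


def plot_path_2d(
    path: ReducedPath,
    out: str | Path,
    overlay: ReducedPath | None = None,
    cmap: str = "viridis",
) -> Path:
    """Plot PC1 vs PC2 as a start-to-end color-mapped line; an optional
    second path (e.g. a trajectory projected into an IRC space) is overlaid
    with a black outline."""
    if path.n_dim < 2:
        raise ValueError("2-D plot needs n_dim >= 2")
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    for p, outline in ((path, False), (overlay, True)) if overlay else ((path, False),):
        if p is None:
            continue
        segs = _segments(p.scores[:, :2])
        lc = LineCollection(
            segs, cmap=cmap, array=np.arange(len(segs)),
            linewidths=3.5 if outline else 2.0,
        )
        if outline:
            ax.add_collection(
                LineCollection(segs, colors="black", linewidths=5.0, zorder=1)
            )
            lc.set_zorder(2)
        ax.add_collection(lc)
    allpts = np.vstack(
        [path.scores[:, :2]] + ([overlay.scores[:, :2]] if overlay else [])
    )
    ax.update_datalim(allpts)
    ax.autoscale_view()
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_title(path.label)
    fig.tight_layout()
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out


def plot_path_3d(
    path: ReducedPath,
    out: str | Path,
    overlay: ReducedPath | None = None,
    cmap: str = "viridis",
) -> Path:
    """Plot PC1-PC3 as a 3-D color-mapped line."""
    if path.n_dim < 3:
        raise ValueError("3-D plot needs n_dim >= 3")
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    for p in (path, overlay):
        if p is None:
            continue
        segs = _segments(p.scores[:, :3])
        lc = Line3DCollection(segs, cmap=cmap, array=np.arange(len(segs)), linewidths=2.0)
        ax.add_collection3d(lc)
    allpts = np.vstack(
        [path.scores[:, :3]] + ([overlay.scores[:, :3]] if overlay else [])
    )
    for setter, col in zip(("set_xlim", "set_ylim", "set_zlim"), allpts.T):
        lo, hi = col.min(), col.max()
        pad = 0.05 * (hi - lo or 1.0)
        getattr(ax, setter)(lo - pad, hi + pad)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    ax.set_zlabel("PC3")
    ax.set_title(path.label)
    out = Path(out)
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
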