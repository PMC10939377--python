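"""Optional plotting helpers (never inputs to any computation)."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .outcomes import PhaseDiagram
from .protocol import Trajectory

_CATEGORY_COLORS = {
    "coexistence": "#2a9d8f",
    "exclusion": "#e76f51",
    "collapse": "#264653",
    "error": "#aaaaaa",
}


def plot_trajectory(traj: Trajectory, ax=None, log: bool = True):
    """Abundance time series, one line per member."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    for j, name in enumerate(traj.member_names):
        ax.plot(traj.times, traj.abundances[:, j], label=name)
    window = traj.metadata.get("protocol", {}).get("antibiotic_window")
    if window:
        ax.axvspan(window[0], window[1], color="pink", alpha=0.4,
                   label="antibiotic pulse")
    if log:
        ax.set_yscale("log")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("normalized abundance")
    ax.legend(fontsize=8)
    return ax


def plot_phase_diagram(diagram: PhaseDiagram, ax=None,
                       color_by: str = "category"):
    """Raster of a categorical outcome grid."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4.5))
    grid = diagram.category if color_by == "category" else diagram.dominant
    labels = sorted({str(v) for row in grid for v in row})
    index = {lab: i for i, lab in enumerate(labels)}
    numeric = np.array([[index[str(v)] for v in row] for row in grid])
    colors = [
        _CATEGORY_COLORS.get(lab, f"C{i}") for i, lab in enumerate(labels)
    ]
    ax.pcolormesh(
        diagram.axes[1].values, diagram.axes[0].values, numeric,
        cmap=ListedColormap(colors), shading="nearest",
    )
    if diagram.axes[0].scale == "log":
        ax.set_yscale("log")
    if diagram.axes[1].scale == "log":
        ax.set_xscale("log")
    ax.set_xlabel(diagram.axes[1].name)
    ax.set_ylabel(diagram.axes[0].name)
    handles = [
        __import__("matplotlib.patches", fromlist=["Patch"]).Patch(
            color=colors[i], label=lab
        )
        for i, lab in enumerate(labels)
    ]
    ax.legend(handles=handles, fontsize=7, loc="upper right")
    return ax
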