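"""Morphospace and trajectory plots (matplotlib, Agg-safe)."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .gating import GatingModel
from .tracking import Trajectory

__all__ = ["plot_morphospace", "plot_trajectory"]


def plot_morphospace(
    frame: pd.DataFrame,
    model: GatingModel,
    path: Union[str, Path],
    hue: str = "morpho_class",
    title: str = "",
) -> None:
    """Area vs irregularity scatter with the normal ellipse and thresholds overlaid.

    The upper-right quadrant beyond the area threshold splits into the F-state
    (large regular, below the irregularity threshold) and E-state (large
    irregular) regions.
    """
    fig, ax = plt.subplots(figsize=(7, 5))
    if hue in frame.columns:
        for value, grp in frame.groupby(hue):
            ax.scatter(grp["area"], grp["irregularity"], s=8, alpha=0.6, label=str(value))
        ax.legend(title=hue, fontsize=8)
    else:
        ax.scatter(frame["area"], frame["irregularity"], s=8, alpha=0.6)
    boundary = model.ellipse.boundary(n=256)
    ax.plot(np.append(boundary[:, 0], boundary[0, 0]),
            np.append(boundary[:, 1], boundary[0, 1]), "k-", lw=1.5, label="normal ellipse")
    for x in (model.area_low, model.area_high):
        ax.axvline(x, color="gray", ls="--", lw=1)
    ax.axhline(model.irr_threshold, color="gray", ls=":", lw=1)
    ymax = max(frame["irregularity"].max(), model.irr_threshold) * 1.05
    ax.text(model.area_high, ymax, " E-state (LI)", va="top", fontsize=8)
    ax.text(model.area_high, model.irr_threshold, " F-state (LR)", va="top", fontsize=8)
    ax.set_xlabel("area (px²)")
    ax.set_ylabel("irregularity index")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_trajectory(
    trajectories: Sequence[Trajectory],
    model: GatingModel,
    path: Union[str, Path],
    max_tracks: int = 20,
) -> None:
    """Per-track morphospace paths with start (red) and end (blue) markers."""
    fig, ax = plt.subplots(figsize=(7, 5))
    for traj in list(trajectories)[:max_tracks]:
        a, irr = traj.areas, traj.irregularities
        ax.plot(a, irr, "-", lw=0.8, alpha=0.6)
        ax.plot(a[0], irr[0], "o", color="red", ms=4)
        ax.plot(a[-1], irr[-1], "o", color="blue", ms=4)
    boundary = model.ellipse.boundary(n=256)
    ax.plot(np.append(boundary[:, 0], boundary[0, 0]),
            np.append(boundary[:, 1], boundary[0, 1]), "k-", lw=1.5)
    for x in (model.area_low, model.area_high):
        ax.axvline(x, color="gray", ls="--", lw=1)
    ax.axhline(model.irr_threshold, color="gray", ls=":", lw=1)
    ax.set_xlabel("area (px²)")
    ax.set_ylabel("irregularity index")
    ax.set_title("single-cell morphospace trajectories (red: start, blue: end)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
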