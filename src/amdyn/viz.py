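"""Minimal numeric scalp visualization.

Renders a per-channel scalar (typically a prestige component) as a 2-D
scatter over electrode positions.  Only the values matter here — full
topographic interpolation and styling belong to dedicated EEG plotting
tools.
"""

from __future__ import annotations

import numpy as np

#: Approximate 2-D positions (x: left-right, y: back-front) for the
#: default ten-electrode subset of the 10-20 layout.
DEFAULT_POSITIONS: dict[str, tuple[float, float]] = {
    "F7": (-0.7, 0.6), "F8": (0.7, 0.6),
    "T7": (-0.9, 0.0), "T8": (0.9, 0.0),
    "C3": (-0.45, 0.0), "C4": (0.45, 0.0),
    "P7": (-0.7, -0.6), "P8": (0.7, -0.6),
    "O1": (-0.3, -0.9), "O2": (0.3, -0.9),
}


def plot_channel_scores(scores: dict[str, float],
                        positions: dict[str, tuple[float, float]] | None = None,
                        ax=None, title: str | None = None):
    """Scatter per-channel scores on a schematic scalp.

    Parameters
    ----------
    scores
        Mapping channel label -> scalar value.
    positions
        Mapping label -> (x, y); defaults to the ten-electrode layout.
    ax
        Existing matplotlib axes (a new figure otherwise).

    Returns the axes.
    """
    import matplotlib.pyplot as plt

    positions = positions or DEFAULT_POSITIONS
    missing = [ch for ch in scores if ch not in positions]
    if missing:
        raise KeyError(f"no scalp position for channels {missing}")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    xy = np.array([positions[ch] for ch in scores])
    vals = np.array(list(scores.values()), dtype=float)
    sc = ax.scatter(xy[:, 0], xy[:, 1], c=vals, s=400, cmap="viridis",
                    edgecolors="k")
    for (x, y), ch in zip(xy, scores):
        ax.annotate(ch, (x, y), ha="center", va="center", fontsize=7)
    circle = plt.Circle((0, 0), 1.05, fill=False, color="gray")
    ax.add_patch(circle)
    ax.set_xlim(-1.2, 1.2)
    ax.set_ylim(-1.2, 1.2)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    plt.colorbar(sc, ax=ax, shrink=0.7)
    return ax
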