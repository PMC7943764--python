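"""Minimal plotting helpers: potency heatmaps and uniqueness/shareability
triangles."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_potency_matrix", "plot_triangle"]


def plot_potency_matrix(matrix: np.ndarray, ax=None, title: str = ""):
    """Heatmap of a (group-mean) potency matrix, symmetric colour scale."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    v = float(np.nanmax(np.abs(matrix))) or 1.0
    im = ax.imshow(matrix, cmap="RdBu_r", vmin=-v, vmax=v)
    ax.set_xlabel("region")
    ax.set_ylabel("region")
    if title:
        ax.set_title(title)
    ax.figure.colorbar(im, ax=ax, label="potency (z*)")
    return ax


def plot_triangle(coords: np.ndarray, ax=None, label_a: str = "A", label_b: str = "B"):
    """Scatter of per-edge (uniqueness, shareability) coordinates inside the
    y <= 1 - |x| triangle for one group pair."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    coords = np.asarray(coords)
    ax.plot([-1, 0, 1, -1], [0, 1, 0, 0], color="0.6", lw=1)
    ax.scatter(coords[:, 0], coords[:, 1], s=6, alpha=0.5)
    ax.set_xlim(-1.05, 1.05)
    ax.set_ylim(-0.05, 1.05)
    ax.set_xlabel(f"uniqueness: rate({label_a}) - rate({label_b})")
    ax.set_ylabel("shareability (shared selection rate)")
    return ax
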