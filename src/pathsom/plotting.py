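"""Static diagnostic plots: cluster scatter for 2-D data and a
connectivity heatmap."""

from __future__ import annotations

import numpy as np

from .containers import ConnectivityMatrix, ExpressionMatrix, Partition

__all__ = ["plot_clusters", "plot_rho"]


def plot_clusters(data: ExpressionMatrix, partition: Partition,
                  weights: np.ndarray | None = None, ax=None):
    """Scatter of 2-D patterns coloured by cluster, prototypes as black
    dots.  Only defined for exactly two conditions."""
    import matplotlib.pyplot as plt
    if data.n_conditions != 2:
        raise ValueError("cluster scatter requires exactly 2 conditions")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    ax.scatter(data.values[:, 0], data.values[:, 1],
               c=partition.labels, cmap="tab20", s=12, alpha=0.8)
    if weights is not None:
        ax.scatter(weights[:, 0], weights[:, 1], c="black", s=40, zorder=3)
    ax.set_xlabel(data.condition_names[0])
    ax.set_ylabel(data.condition_names[1])
    return ax


def plot_rho(conn: ConnectivityMatrix, order: np.ndarray | None = None,
             upper_triangular: bool = True, ax=None):
    """Heatmap of the shared-pathway matrix (optionally row-reordered,
    e.g. by connectivity set, and masked to the upper triangle)."""
    import matplotlib.pyplot as plt
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    rho = conn.rho.astype(float)
    if order is not None:
        rho = rho[np.ix_(order, order)]
    if upper_triangular:
        rho = np.triu(rho)
    ax.imshow(rho, cmap="Greys", interpolation="nearest")
    ax.set_xlabel("pattern")
    ax.set_ylabel("pattern")
    return ax
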