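"""Display helpers.  Log scaling of connectivity lives here only; stored
matrices always hold raw fractions."""

from __future__ import annotations

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import LogNorm

from .connectivity_metrics import ConnectivityMatrix, DispersalKernel


def plot_connectivity(C: ConnectivityMatrix, ax=None, vmin: float = 1e-6):
    """Heatmap of a connectivity matrix on a log colour scale; sources on
    the y-axis, sinks on the x-axis, local retention on the diagonal."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    vals = np.where(C.values > 0, C.values, np.nan)
    im = ax.imshow(vals, origin="lower", aspect="auto",
                   norm=LogNorm(vmin=vmin, vmax=max(np.nanmax(vals), vmin * 10)))
    ax.set_xlabel("receiving site")
    ax.set_ylabel("source site")
    ax.set_title(f"{C.kind} connectivity")
    plt.colorbar(im, ax=ax, label="settlement fraction")
    return ax


def plot_kernels(kernels: list[DispersalKernel], ax=None):
    """Step plot of dispersal kernels (proportion vs distance)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for k in kernels:
        ax.stairs(k.proportions, k.bin_edges_km, label=k.group)
    ax.set_xlabel("distance from release (km)")
    ax.set_ylabel("settlement proportion")
    ax.legend()
    return ax
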