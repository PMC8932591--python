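"""Presentation-only plotting helpers (requires the ``plot`` extra)."""

from __future__ import annotations

import numpy as np
import pandas as pd

_PHASE_COLORS = {
    "Schooling": "#d62728",
    "Milling": "#1f77b4",
    "Intermittent": "#17becf",
    "Swarming": "#2ca02c",
    "Dispersion": "#7f7f7f",
}


def plot_phase_diagram(grid: pd.DataFrame, path=None):
    """Raster of phase labels over the (gamma_att, gamma_ali) grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for label, color in _PHASE_COLORS.items():
        sub = grid[grid["phase_label"] == label]
        ax.scatter(sub["gamma_att"], sub["gamma_ali"], c=color, marker="s",
                   s=80, label=label)
    ax.set_xlabel(r"$\gamma_{\mathrm{Att}}$")
    ax.set_ylabel(r"$\gamma_{\mathrm{Ali}}$")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_density_map(hist: np.ndarray, edges: np.ndarray, path=None):
    """Heatmap of an influential-neighbor position density (focal at origin)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.imshow(hist.T, origin="lower",
              extent=[edges[0], edges[-1], edges[0], edges[-1]])
    ax.plot([0], [0], "r^")
    ax.set_xlabel("x (m)")
    ax.set_ylabel("y (m), focal heading north")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
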