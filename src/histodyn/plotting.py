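"""Basic figures: metaprofiles, turnover-sorted heatmaps, score histograms.

Deliberately minimal styling; color scaling is global by default with a
per-row option.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .profiles import TSSMatrix

__all__ = ["plot_metaprofiles", "plot_heatmap", "plot_score_histogram"]


def plot_metaprofiles(profiles: dict[str, np.ndarray], bin_size: int = 20,
                      flank: int = 4000, ylabel: str = "log2 enrichment", path=None):
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for label, values in profiles.items():
        values = np.asarray(values, dtype=float)
        x = np.arange(len(values)) * bin_size - flank
        ax.plot(x, values, label=label, lw=1.2)
    ax.axvline(0, color="grey", lw=0.6, ls="--")
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel(ylabel)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_heatmap(matrix: TSSMatrix, row_order=None, per_row: bool = False, path=None):
    values = matrix.values
    if row_order is not None:
        values = values[np.asarray(row_order)]
    if per_row:
        lo = np.nanmin(values, axis=1, keepdims=True)
        hi = np.nanmax(values, axis=1, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        values = (values - lo) / span
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(values, aspect="auto", interpolation="nearest", cmap="viridis",
                   extent=[-matrix.flank, matrix.flank, len(values), 0])
    fig.colorbar(im, ax=ax, shrink=0.6)
    ax.set_xlabel("distance from TSS (bp)")
    ax.set_ylabel("genes")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_score_histogram(hist, labels=("a", "b"), path=None):
    fig, ax = plt.subplots(figsize=(4.5, 3))
    centers = 0.5 * (hist["bin_left"] + hist["bin_right"])
    width = (hist["bin_right"] - hist["bin_left"]).iloc[0]
    ax.bar(centers - width / 4, hist["count_a"], width=width / 2, label=labels[0])
    ax.bar(centers + width / 4, hist["count_b"], width=width / 2, label=labels[1])
    ax.set_xlabel("turnover score")
    ax.set_ylabel("loci")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
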