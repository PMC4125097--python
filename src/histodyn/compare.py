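"""Two-cell-type comparisons: promoter selection, deltas, tile-level gains.

Delta convention throughout: second cell type minus first (gain-positive for
the second), stamped into output column names. Promoter summaries entering a
comparison are first normalized to each cell type's own mean unmasked-tile
signal, so a global abundance difference between cell types does not masquerade
as locus-specific change.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import running_window
from .turnover import correlate

__all__ = [
    "select_expressed_promoters",
    "celltype_normalize",
    "delta_sort_report",
    "density_vs_delta",
]


def select_expressed_promoters(summary_a: pd.Series, summary_b: pd.Series,
                               threshold: float = 0.1) -> pd.Index:
    """Genes whose promoter summary reaches ``threshold`` in either cell type.

    The two summaries must cover the same gene universe. The threshold is
    boundary-inclusive.
    """
    if not summary_a.index.sort_values().equals(summary_b.index.sort_values()):
        raise ValueError("summaries are not on the same gene universe")
    b = summary_b.reindex(summary_a.index)
    best = np.fmax(summary_a.to_numpy(dtype=float), b.to_numpy(dtype=float))
    keep = best >= threshold
    return summary_a.index[keep]


def celltype_normalize(summary: pd.Series, tiles: pd.DataFrame) -> pd.Series:
    """Express a promoter summary relative to the cell type's own average level.

    The base is the mean signal over unmasked tiles, converted to the
    summary's per-bin scale (tile signal is a sum of bins). Zero base raises.
    """
    unmasked = tiles[tiles["mask"] == "ok"]
    if unmasked.empty:
        raise ValueError("no unmasked tiles to define the normalization base")
    bins_per_tile = (unmasked["end"] - unmasked["start"]).iloc[0] / 20
    base = float(unmasked["signal"].mean()) / bins_per_tile
    if base <= 0:
        raise ValueError("cell-type mean signal is zero; cannot normalize")
    return summary / base


def delta_sort_report(comparison: pd.DataFrame, window: int = 100) -> pd.DataFrame:
    """Sort genes by delta and attach a running-window mean of first-type turnover.

    ``comparison`` needs columns ``delta`` and ``turnover_a``. The window is
    clipped to the table size (a 2-gene table with the default window of 100 is
    still valid).
    """
    if comparison.empty:
        raise ValueError("comparison table is empty")
    for col in ("delta", "turnover_a"):
        if col not in comparison.columns:
            raise ValueError(f"comparison table lacks column {col!r}")
    out = comparison.sort_values("delta", kind="stable").copy()
    w = min(window, len(out))
    out["turnover_a_running"] = running_window(out["turnover_a"].to_numpy(), w)
    return out


def build_comparison(summary_a: pd.Series, summary_b: pd.Series,
                     turnover_a: pd.Series, turnover_b: pd.Series,
                     tiles_a: pd.DataFrame, tiles_b: pd.DataFrame,
                     threshold: float = 0.1) -> pd.DataFrame:
    """Assemble the per-gene comparison table (selection + normalization + delta)."""
    keep = select_expressed_promoters(summary_a, summary_b, threshold=threshold)
    norm_a = celltype_normalize(summary_a, tiles_a).reindex(keep)
    norm_b = celltype_normalize(summary_b, tiles_b).reindex(keep)
    return pd.DataFrame({
        "summary_a": summary_a.reindex(keep),
        "summary_b": summary_b.reindex(keep),
        "norm_a": norm_a,
        "norm_b": norm_b,
        "delta": norm_b - norm_a,       # gain-positive for cell type b
        "turnover_a": turnover_a.reindex(keep),
        "turnover_b": turnover_b.reindex(keep),
    })


def density_vs_delta(tiles_a: pd.DataFrame, tiles_b: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-tile normalized delta (b - a) with gene-density decile summaries.

    Both TileTables must share the tile grid and be masked; a tile masked in
    either cell type is dropped. Each cell type's tile signals are first
    divided by its own unmasked mean. The summary reports the mean gene count
    of the top and bottom delta deciles.
    """
    if len(tiles_a) != len(tiles_b) or not (
        (tiles_a["chrom"].to_numpy() == tiles_b["chrom"].to_numpy()).all()
        and (tiles_a["start"].to_numpy() == tiles_b["start"].to_numpy()).all()
    ):
        raise ValueError("tile grids do not match")
    ok = (tiles_a["mask"].to_numpy() == "ok") & (tiles_b["mask"].to_numpy() == "ok")
    if not ok.any():
        raise ValueError("no shared unmasked tiles")
    a = tiles_a.loc[ok].reset_index(drop=True)
    b = tiles_b.loc[ok].reset_index(drop=True)
    norm_a = a["signal"].to_numpy() / a["signal"].mean()
    norm_b = b["signal"].to_numpy() / b["signal"].mean()
    delta = norm_b - norm_a
    table = pd.DataFrame({
        "chrom": a["chrom"],
        "start": a["start"],
        "end": a["end"],
        "gene_count": a["gene_count"],
        "norm_a": norm_a,
        "norm_b": norm_b,
        "delta": delta,
    })
    n_dec = max(1, len(table) // 10)
    order = np.argsort(delta, kind="stable")
    top = table.iloc[order[-n_dec:]]      # largest gains in cell type b
    bottom = table.iloc[order[:n_dec]]
    try:
        rho = correlate(table["delta"], table["gene_count"], method="spearman")
    except ValueError:  # degenerate (constant or tiny) input: no correlation defined
        rho = None
    summary = {
        "n_tiles": int(len(table)),
        "top_decile_mean_gene_count": float(top["gene_count"].mean()),
        "bottom_decile_mean_gene_count": float(bottom["gene_count"].mean()),
        "delta_gene_count_spearman": rho,
    }
    return table, summary
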