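"""TSS-aligned matrices, metaprofiles, promoter summaries, clusters, quintiles.

The central object is a genes x positional-bins matrix spanning -4 kb..+4 kb
around each TSS in 20-bp bins, oriented so positive offsets are downstream of
transcription (minus-strand rows are reversed). Bin 200 starts at the TSS.
Out-of-chromosome positions are NaN (missing), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from . import io as hio
from .coverage import CoverageTrack
from .simulate import GenomeAnnotation

__all__ = [
    "TSSMatrix",
    "tss_matrix",
    "anchor_matrix",
    "flank_normalize",
    "meta_average",
    "promoter_summary",
    "cluster_and_merge",
    "running_window",
    "expression_quintiles",
]


@dataclass
class TSSMatrix:
    """Genes x positional bins, strand-oriented; NaN marks missing cells."""

    gene_ids: list[str]
    values: np.ndarray          # (n_genes, n_bins) float
    bin_size: int = 20
    flank: int = 4000
    log_scale: bool = False

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def center_bin(self) -> int:
        return self.flank // self.bin_size

    def bin_index(self, offset: int) -> int:
        """Bin whose span contains the transcription-relative offset (bp)."""
        if not (-self.flank <= offset < self.flank):
            raise ValueError(f"offset {offset} outside +/-{self.flank}")
        return (offset + self.flank) // self.bin_size

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]

    def subset(self, gene_subset: Sequence[str]) -> "TSSMatrix":
        pos = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_subset if g not in pos]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        idx = [pos[g] for g in gene_subset]
        return replace(self, gene_ids=list(gene_subset), values=self.values[idx].copy())

    def to_tsv(self, path, header: Mapping[str, object] | None = None) -> None:
        meta = {
            "span": f"-{self.flank}..{self.flank}",
            "bin_size": self.bin_size,
            "orientation": "transcription (minus-strand rows reversed); "
                           f"units={'log2-ratio' if self.log_scale else 'ppm'}",
        }
        meta.update(header or {})
        offsets = [self.bin_size * i - self.flank for i in range(self.n_bins)]
        df = pd.DataFrame(self.values, index=pd.Index(self.gene_ids, name="gene_id"),
                          columns=[str(o) for o in offsets])
        hio.write_tsv(df, path, header=meta, index=True)

    @classmethod
    def from_tsv(cls, path) -> "TSSMatrix":
        meta = hio.read_header(path)
        df = hio.read_tsv(path, index_col=0)
        bin_size = int(meta.get("bin_size", 20))
        flank = -int(df.columns[0])
        log_scale = "log2" in meta.get("orientation", "")
        return cls(gene_ids=[str(g) for g in df.index], values=df.to_numpy(dtype=float),
                   bin_size=bin_size, flank=flank, log_scale=log_scale)


def _extract_windows(track: CoverageTrack, chroms: Sequence[str], centers: np.ndarray,
                     half_span: int, bin_size: int) -> np.ndarray:
    """Window rows in genome orientation; positions past chromosome ends are NaN.

    Each output bin is the track bin containing the output bin's midpoint —
    exact whenever the center is aligned to the track grid.
    """
    n_bins = 2 * half_span // bin_size
    offsets = np.arange(n_bins) * bin_size - half_span + bin_size // 2
    out = np.full((len(centers), n_bins), np.nan)
    centers = np.asarray(centers, dtype=np.int64)
    chrom_arr = np.asarray(chroms, dtype=object)
    for chrom in pd.unique(chrom_arr):
        if chrom not in track.data:
            raise ValueError(f"unknown chromosome {chrom!r} in track")
        sel = np.flatnonzero(chrom_arr == chrom)
        pos = centers[sel][:, None] + offsets[None, :]
        valid = (pos >= 0) & (pos < track.chrom_sizes[chrom])
        idx = np.clip(pos // track.bin_size, 0, len(track.data[chrom]) - 1)
        vals = track.data[chrom][idx]
        vals[~valid] = np.nan
        out[sel] = vals
    return out


def tss_matrix(track: CoverageTrack, annotation: GenomeAnnotation,
               flank: int = 4000) -> TSSMatrix:
    """Strand-oriented TSS windows (default -4 kb..+4 kb, 400 bins of 20 bp)."""
    if flank % track.bin_size != 0:
        raise ValueError("bin size must divide flank")
    genes = annotation.genes
    if genes.empty:
        raise ValueError("annotation has no genes")
    unknown = set(genes["chrom"]) - set(track.chrom_sizes)
    if unknown:
        raise ValueError(f"genes on chromosomes absent from track: {sorted(unknown)}")
    values = _extract_windows(track, genes["chrom"].tolist(), genes["tss"].to_numpy(),
                              flank, track.bin_size)
    minus = (genes["strand"] == "-").to_numpy()
    values[minus] = values[minus, ::-1]
    return TSSMatrix(gene_ids=genes["gene_id"].tolist(), values=values,
                     bin_size=track.bin_size, flank=flank)


def anchor_matrix(track: CoverageTrack, anchors: Sequence[tuple[str, int]],
                  span: int = 8000) -> TSSMatrix:
    """Unoriented windows of ``span`` bp centered on (chrom, midpoint) anchors."""
    if not anchors:
        raise ValueError("empty anchor list")
    if span % (2 * track.bin_size) != 0:
        raise ValueError("span must be an even multiple of the bin size")
    chroms = [a[0] for a in anchors]
    centers = np.asarray([a[1] for a in anchors], dtype=np.int64)
    for chrom, mid in anchors:
        if chrom not in track.chrom_sizes:
            raise ValueError(f"anchor on unknown chromosome {chrom!r}")
        if not (0 <= mid < track.chrom_sizes[chrom]):
            raise ValueError(f"anchor midpoint {mid} outside {chrom}")
    values = _extract_windows(track, chroms, centers, span // 2, track.bin_size)
    ids = [f"{c}:{m}" for c, m in anchors]
    return TSSMatrix(gene_ids=ids, values=values, bin_size=track.bin_size, flank=span // 2)


def flank_normalize(matrix: TSSMatrix, flank_window: tuple[int, int] = (-4000, -2000),
                    pseudocount: float = 0.01, log: bool = True,
                    ) -> tuple[TSSMatrix, np.ndarray]:
    """Normalize each row to its upstream-flank mean; optionally log2.

    Values become ``log2(max(v, pseudocount) / m)`` with ``m`` the row's mean
    over the flank window (the pseudocount floors the numerator only, so e.g. a
    value of 8 against a flank mean of 2 is exactly 2.0). Rows whose flank mean
    is <= pseudocount are flagged and set to NaN. Returns (matrix, flagged).
    The default window follows the -4..-2 kb convention; (-2500, -1500) is the
    grouped-profile alternative.
    """
    lo, hi = flank_window
    if not (-matrix.flank <= lo < hi <= matrix.flank):
        raise ValueError(f"flank window {flank_window} outside matrix span")
    j0 = (lo + matrix.flank) // matrix.bin_size
    j1 = (hi + matrix.flank) // matrix.bin_size
    if j1 <= j0:
        raise ValueError("empty flank window")
    with np.errstate(invalid="ignore"):
        m = np.nanmean(matrix.values[:, j0:j1], axis=1)
    flagged = ~np.isfinite(m) | (m <= pseudocount)
    out = np.full_like(matrix.values, np.nan)
    ok = ~flagged
    ratio = np.maximum(matrix.values[ok], pseudocount) / m[ok, None]
    out[ok] = np.log2(ratio) if log else ratio
    return (replace(matrix, values=out, log_scale=log), flagged)


def meta_average(matrix: TSSMatrix, gene_subset: Sequence[str] | None = None) -> np.ndarray:
    """Per-bin mean profile over a gene subset, ignoring missing cells."""
    sub = matrix if gene_subset is None else matrix.subset(list(gene_subset))
    if sub.values.shape[0] == 0:
        raise ValueError("empty gene subset")
    with np.errstate(invalid="ignore"):
        return np.nanmean(sub.values, axis=0)


def promoter_summary(matrix: TSSMatrix, window: tuple[int, int] = (-600, 600)) -> pd.Series:
    """Per-gene mean over the promoter window (default -600..+600 bp, 60 bins).

    The mean (not the sum) keeps the value depth- and width-independent, so the
    downstream >= 0.1 selection threshold is scale-free. Genes whose window is
    entirely missing get NaN.
    """
    lo, hi = window
    j0 = (lo + matrix.flank) // matrix.bin_size
    j1 = (hi + matrix.flank) // matrix.bin_size
    if not (0 <= j0 < j1 <= matrix.n_bins):
        raise ValueError(f"promoter window {window} outside matrix span")
    with np.errstate(invalid="ignore"):
        vals = np.nanmean(matrix.values[:, j0:j1], axis=1)
    return pd.Series(vals, index=pd.Index(matrix.gene_ids, name="gene_id"), name="promoter_mean")


def cluster_and_merge(matrix: TSSMatrix, k: int = 4, merge_r: float = 0.90,
                      seed: int = 0) -> np.ndarray:
    """k-means on rows, then merge clusters whose centroids correlate >= merge_r.

    Returns integer labels, renumbered so label 0 is the largest merged group.
    Rows must be finite. Deterministic for a fixed seed.
    """
    X = matrix.values
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds number of rows {X.shape[0]}")
    if not np.isfinite(X).all():
        raise ValueError("matrix rows must be finite for clustering")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(X)
    centers = km.cluster_centers_

    parent = list(range(k))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a in range(k):
        for b in range(a + 1, k):
            ca, cb = centers[a], centers[b]
            if np.std(ca) == 0 or np.std(cb) == 0:
                r = 1.0 if np.allclose(ca, cb) else 0.0
            else:
                r = float(np.corrcoef(ca, cb)[0, 1])
            if r >= merge_r:
                parent[find(a)] = find(b)

    merged = np.array([find(l) for l in labels])
    roots, counts = np.unique(merged, return_counts=True)
    order = roots[np.argsort(-counts, kind="stable")]
    remap = {root: i for i, root in enumerate(order)}
    return np.array([remap[m] for m in merged], dtype=int)


def running_window(values, w: int) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    if w < 1:
        raise ValueError("window must be >= 1")
    if w > n:
        raise ValueError(f"window {w} exceeds series length {n}")
    return (pd.Series(values).rolling(window=w, center=True, min_periods=1)
            .mean().to_numpy())


def expression_quintiles(summary: pd.Series, annotation: GenomeAnnotation) -> pd.DataFrame:
    """Boxplot statistics of a promoter summary per expression quintile.

    Genes are sorted by expression (stable, so ties keep gene order) and split
    into 5 near-equal groups from bottom 20% to top 20%. Each row reports
    median, Q1, Q3, mean, and sd of the summary.
    """
    expr = annotation.genes.set_index("gene_id")["expression"]
    missing = summary.index.difference(expr.index)
    if len(missing):
        raise ValueError(f"no expression for genes: {list(missing[:5])}")
    if len(summary) < 5:
        raise ValueError("need at least 5 genes for quintiles")
    expr = expr.reindex(summary.index)
    order = np.argsort(expr.to_numpy(), kind="stable")
    groups = np.array_split(order, 5)
    rows = []
    for i, idx in enumerate(groups):
        vals = summary.to_numpy()[idx]
        vals = vals[np.isfinite(vals)]
        rows.append({
            "quintile": i + 1,
            "n": len(idx),
            "median": float(np.median(vals)),
            "q1": float(np.percentile(vals, 25)),
            "q3": float(np.percentile(vals, 75)),
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
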