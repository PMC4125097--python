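"""Forward simulator of epitope-tag incorporation in asynchronous cycling cells.

A synthetic genome carries gene-rich blocks and gene deserts. Every locus gets a
ground-truth exchange rate ``k`` (per hour), a relative nucleosome density
(occupancy), and a replication time within S phase. After induction the soluble
pool of tagged histone rises as ``p(t) = 1 - exp(-(t - t0)/tau)`` (``tau = 0``
gives an instantaneous step). For a single cell observed at cycle phase ``phi``
the tagged fraction of a locus obeys

    dF/dt = k * (p(t) - F),            F(0) = 0,

punctuated by one replication event per cycle at the locus' S-phase offset,
where the parental tagged fraction is diluted and new deposition reflects the
current pool::

    F  <-  r * F + (1 - r) * p(t_rep).

Population-level expected signal averages ``F`` over cells with uniformly
distributed phases. Reads are then drawn per locus from a Poisson distribution
proportional to occupancy x tagged signal x locus width, with uniform fragment
start placement and random strand, and emitted as 6-column BED.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import io as hio

__all__ = [
    "GenomeAnnotation",
    "PoolParams",
    "CellCycleParams",
    "KineticTruth",
    "SimConfig",
    "make_genome",
    "assign_kinetics",
    "pool_fraction",
    "tagged_fraction",
    "population_signal",
    "sample_reads",
    "simulate_experiment",
    "SimResult",
    "timepoint_label",
]

GENE_COLUMNS = ["gene_id", "chrom", "tss", "strand", "expression"]
LOCUS_COLUMNS = [
    "locus_id", "chrom", "start", "end", "occupancy", "k", "rep_offset", "cls", "ambient",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus a gene table (gene_id, chrom, tss, strand, expression)."""

    chrom_sizes: dict[str, int]
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.genes = self.genes.reset_index(drop=True)
        if not self.genes.empty:
            if self.genes["gene_id"].duplicated().any():
                raise ValueError("gene_ids must be unique")
            for chrom, block in self.genes.groupby("chrom", sort=False):
                if chrom not in self.chrom_sizes:
                    raise ValueError(f"gene chromosome {chrom!r} not in chromosome list")
                tss = block["tss"].to_numpy()
                if (tss < 0).any() or (tss >= self.chrom_sizes[chrom]).any():
                    raise ValueError(f"TSS out of bounds on {chrom}")

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_sizes.values()))

    def to_tsv(self, path, header: Mapping[str, object] | None = None) -> None:
        meta = dict(header or {})
        for chrom, size in self.chrom_sizes.items():
            meta[f"chrom:{chrom}"] = size
        hio.write_tsv(self.genes[GENE_COLUMNS] if not self.genes.empty
                      else pd.DataFrame(columns=GENE_COLUMNS), path, header=meta)

    @classmethod
    def from_tsv(cls, path) -> "GenomeAnnotation":
        meta = hio.read_header(path)
        sizes = {k.split(":", 1)[1]: int(v) for k, v in meta.items() if k.startswith("chrom:")}
        if not sizes:
            raise ValueError(f"annotation {path} lacks '# chrom:<name>=<length>' header lines")
        genes = hio.read_tsv(path, dtype={"gene_id": str, "chrom": str, "tss": np.int64,
                                          "strand": str, "expression": float})
        return cls(chrom_sizes=sizes, genes=genes)


@dataclass(frozen=True)
class PoolParams:
    """Soluble tagged-histone pool: delay t0 then saturating rise with time constant tau.

    ``tau = 0`` means an instantaneous step to 1 at t0 (p(t) = 1 for t >= t0).
    """

    t0: float = 0.5
    tau: float = 1.5

    def __post_init__(self) -> None:
        if self.t0 < 0:
            raise ValueError("t0 must be >= 0")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")


@dataclass(frozen=True)
class CellCycleParams:
    """Cycle length T, S-phase window, and parental retention at replication."""

    T: float = 12.0
    s_start: float = 2.0
    s_end: float = 8.0
    retention: float = 0.5

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("cycle length T must be > 0")
        if not (0 <= self.s_start < self.s_end <= self.T):
            raise ValueError("require 0 <= s_start < s_end <= T")
        if not (0 <= self.retention <= 1):
            raise ValueError("retention must be in [0, 1]")


@dataclass
class KineticTruth:
    """Per-locus ground truth: interval, occupancy, exchange rate k, replication offset, class."""

    loci: pd.DataFrame
    chrom_sizes: dict[str, int]

    def __post_init__(self) -> None:
        df = self.loci
        if (df["k"] < 0).any():
            raise ValueError("exchange rates must be >= 0")
        for chrom, block in df.groupby("chrom", sort=False):
            size = self.chrom_sizes[chrom]
            if (block["start"].to_numpy() < 0).any() or (block["end"].to_numpy() > size).any():
                raise ValueError(f"locus interval out of bounds on {chrom}")

    @property
    def widths(self) -> np.ndarray:
        return (self.loci["end"] - self.loci["start"]).to_numpy()

    def to_tsv(self, path, header: Mapping[str, object] | None = None) -> None:
        hio.write_tsv(self.loci[LOCUS_COLUMNS + [c for c in self.loci.columns
                                                 if c not in LOCUS_COLUMNS]],
                      path, header=header)


@dataclass
class SimConfig:
    """All knobs of the synthetic experiment; seeded and serializable."""

    seed: int = 0
    mode: str = "ES"                      # "ES" or "MEF"
    depth: int = 500_000                  # read occurrences per time point
    timepoints: tuple[float, ...] = (0.0, 3.0, 6.0, 12.0)
    fragment_length: int = 150
    read_length: int = 36

    # genome
    n_chroms: int = 2
    chrom_length: int = 12_000_000
    n_genes: int = 1500
    desert_fraction: float = 0.2
    block_size: int = 1_000_000           # slot granularity for deserts / dense blocks
    dense_slot_fraction: float = 0.08
    dense_density_ratio: float = 6.0      # target gene-density fold over genome mean
    expressed_fraction: float = 0.85
    expr_silent_mean: float = 2.0
    expr_silent_sd: float = 0.5
    expr_active_mean: float = 8.0
    expr_active_sd: float = 1.5

    # kinetics
    promoter_width: int = 1200
    promoter_occupancy: float = 3.0
    locus_size: int = 4000
    k_min: float = 0.2
    k_max: float = 2.0
    k_background: float = 0.02
    k_expr_lo: float = 5.0                # expression mapped affinely onto [k_min, k_max]
    k_expr_hi: float = 12.0
    hot_k_threshold: float = 1.0          # designed-hot cut for recovery reporting
    expressed_threshold: float = 5.0
    k_noise: float = 0.0                  # lognormal jitter sd on promoter k (off: monotone)
    rep_timing_jitter: bool = False       # default: single fixed mid-S replication offset

    # nonspecific pulldown / artifacts (drives the no-dox control and the top-1% mask)
    ambient: float = 0.02
    n_artifacts: int = 3
    artifact_strength: float = 50.0

    # MEF mode contrasts
    mef_k_shrink: float = 0.08            # promoter k spread compressed toward...
    mef_k_center: float = 0.35            # ...a static-but-present exchange level
    mef_promoter_loss: float = 0.5        # occupancy loss at the fastest ES promoters
    mef_cold_gain: float = 2.0
    mef_gene_poor_max: int = 1            # windows with <= this many genes convert to cold
    mef_cycle_T: float = 20.0

    pool: PoolParams = field(default_factory=PoolParams)
    cell_cycle: CellCycleParams | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("ES", "MEF"):
            raise ValueError(f"mode must be 'ES' or 'MEF', got {self.mode!r}")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be >= 0")
        if self.fragment_length <= 0:
            raise ValueError("fragment_length must be > 0")
        self.timepoints = tuple(float(t) for t in self.timepoints)
        if self.cell_cycle is None:
            if self.mode == "MEF":
                t = self.mef_cycle_T
                self.cell_cycle = CellCycleParams(T=t, s_start=t / 6, s_end=2 * t / 3)
            else:
                self.cell_cycle = CellCycleParams()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pool"] = asdict(self.pool)
        d["cell_cycle"] = asdict(self.cell_cycle)
        d["timepoints"] = list(self.timepoints)
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if isinstance(d.get("pool"), Mapping):
            d["pool"] = PoolParams(**d["pool"])
        if isinstance(d.get("cell_cycle"), Mapping):
            d["cell_cycle"] = CellCycleParams(**d["cell_cycle"])
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def timepoint_label(t: float) -> str:
    """'no_dox' for t = 0, otherwise e.g. 't3' / 't4.5'."""
    if t == 0:
        return "no_dox"
    return f"t{t:g}"


# ---------------------------------------------------------------------------
# genome synthesis
# ---------------------------------------------------------------------------

def make_genome(config: SimConfig) -> GenomeAnnotation:
    """Build a seeded synthetic genome with gene deserts and gene-rich blocks.

    Chromosomes are partitioned into ``block_size`` slots: a ``desert_fraction``
    of slots carry no genes, a small set of dense slots carry a gene density
    at least ``dense_density_ratio`` times the genome mean, and the remainder
    get the leftover genes. Expression is bimodal (silent vs active).
    """
    rng = np.random.default_rng(config.seed)
    chrom_sizes = {f"chr{i + 1}": int(config.chrom_length) for i in range(config.n_chroms)}

    if config.chrom_length < config.block_size:
        raise ValueError(
            f"chromosome length {config.chrom_length} smaller than block size {config.block_size}"
        )
    slots = []  # (chrom, slot_start)
    for chrom, size in chrom_sizes.items():
        for j in range(size // config.block_size):
            slots.append((chrom, j * config.block_size))
    n_slots = len(slots)

    if config.n_genes == 0:
        genes = pd.DataFrame(columns=GENE_COLUMNS).astype(
            {"tss": np.int64, "expression": float}, errors="ignore")
        return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)

    n_desert = min(n_slots - 1, max(1, round(config.desert_fraction * n_slots))) \
        if config.desert_fraction > 0 else 0
    order = rng.permutation(n_slots)
    desert_idx = set(order[:n_desert].tolist())
    non_desert = [i for i in range(n_slots) if i not in desert_idx]
    n_dense = max(1, round(config.dense_slot_fraction * n_slots))
    n_dense = min(n_dense, len(non_desert))
    dense_idx = set(non_desert[:n_dense])  # 'order' already randomized membership

    non_desert_bases = len(non_desert) * config.block_size
    if config.n_genes > non_desert_bases // 1000:
        raise ValueError(
            f"chromosome length too small to host {config.n_genes} genes "
            f"({non_desert_bases} non-desert bases available)"
        )

    # slot weights: desert 0, normal 1, dense w chosen to hit the density target
    n_normal = len(non_desert) - n_dense
    ratio = config.dense_density_ratio
    if n_slots > ratio * n_dense:
        w_dense = max(ratio * n_normal / (n_slots - ratio * n_dense) * 1.1, 2.0)
    else:
        w_dense = 10.0
    weights = np.zeros(n_slots)
    for i in non_desert:
        weights[i] = w_dense if i in dense_idx else 1.0
    weights /= weights.sum()

    counts = rng.multinomial(config.n_genes, weights)
    chroms, tsss = [], []
    for (chrom, start), cnt in zip(slots, counts):
        if cnt == 0:
            continue
        offsets = rng.integers(0, config.block_size, size=cnt)
        chroms.extend([chrom] * cnt)
        tsss.extend((start + offsets).tolist())
    strands = rng.choice(["+", "-"], size=config.n_genes)
    active = rng.random(config.n_genes) < config.expressed_fraction
    expression = np.where(
        active,
        rng.normal(config.expr_active_mean, config.expr_active_sd, config.n_genes),
        rng.normal(config.expr_silent_mean, config.expr_silent_sd, config.n_genes),
    )
    genes = pd.DataFrame({
        "chrom": chroms,
        "tss": np.asarray(tsss, dtype=np.int64),
        "strand": strands,
        "expression": expression,
    })
    genes = genes.sort_values(["chrom", "tss"], kind="stable").reset_index(drop=True)
    genes.insert(0, "gene_id", [f"g{i:05d}" for i in range(len(genes))])
    return GenomeAnnotation(chrom_sizes=chrom_sizes, genes=genes)


# ---------------------------------------------------------------------------
# kinetic truth
# ---------------------------------------------------------------------------

def _window_gene_counts(annotation: GenomeAnnotation, window: int = 100_000) -> dict[str, np.ndarray]:
    out = {}
    for chrom, size in annotation.chrom_sizes.items():
        n = size // window
        counts = np.zeros(n, dtype=np.int64)
        if not annotation.genes.empty:
            tss = annotation.genes.loc[annotation.genes["chrom"] == chrom, "tss"].to_numpy()
            tss = tss[tss < n * window]
            np.add.at(counts, tss // window, 1)
        out[chrom] = counts
    return out


def _desert_intervals(counts: np.ndarray, window: int, min_windows: int = 5) -> list[tuple[int, int]]:
    """Maximal runs of >= min_windows consecutive zero-gene windows."""
    out = []
    run = 0
    for i, c in enumerate(list(counts) + [1]):  # sentinel closes trailing run
        if c == 0:
            run += 1
        else:
            if run >= min_windows:
                out.append(((i - run) * window, i * window))
            run = 0
    return out


def _tile_interval(start: int, end: int, size: int) -> list[tuple[int, int]]:
    edges = list(range(start, end, size)) + [end]
    tiles = [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]
    # merge a short trailing sliver into its neighbour
    if len(tiles) >= 2 and tiles[-1][1] - tiles[-1][0] < size // 2:
        tiles[-2] = (tiles[-2][0], tiles[-1][1])
        tiles.pop()
    return tiles


def assign_kinetics(annotation: GenomeAnnotation, config: SimConfig) -> KineticTruth:
    """Attach ground-truth kinetics to a genome.

    Expressed genes get a ``hot_promoter`` locus (~``promoter_width`` centered
    on the TSS) whose k rises monotonically with expression; gene deserts are
    tiled with near-zero-k ``cold_block`` loci; everything else is
    ``background``. MEF mode shrinks promoter k toward background and adds
    cold blocks (with an occupancy gain) over gene-poor regions.
    """
    if not annotation.chrom_sizes:
        raise ValueError("annotation has no chromosomes")
    rng = np.random.default_rng((config.seed, 7))
    window = 100_000
    win_counts = _window_gene_counts(annotation, window)

    rows = []
    half = config.promoter_width // 2

    def k_of_expression(expr: np.ndarray) -> np.ndarray:
        u = np.clip((expr - config.k_expr_lo) / (config.k_expr_hi - config.k_expr_lo), 0.0, 1.0)
        return config.k_min + (config.k_max - config.k_min) * u

    # promoters
    if not annotation.genes.empty:
        expressed = annotation.genes[annotation.genes["expression"] >= config.expressed_threshold]
        k_prom = k_of_expression(expressed["expression"].to_numpy())
        if config.k_noise > 0:
            k_prom = k_prom * np.exp(rng.normal(0.0, config.k_noise, size=k_prom.size))
            k_prom = np.clip(k_prom, config.k_background, None)
        occ_prom = np.full(k_prom.size, config.promoter_occupancy)
        if config.mode == "MEF":
            # spread compresses toward a static level; the fastest ES promoters
            # lose occupancy upon differentiation
            u = (k_prom - config.k_min) / max(config.k_max - config.k_min, 1e-12)
            occ_prom = config.promoter_occupancy * (1.0 - config.mef_promoter_loss
                                                    * np.clip(u, 0.0, 1.0))
            k_prom = config.mef_k_center + config.mef_k_shrink * (k_prom - config.mef_k_center)
        for (_, gene), k, occ in zip(expressed.iterrows(), k_prom, occ_prom):
            size = annotation.chrom_sizes[gene["chrom"]]
            start = max(int(gene["tss"]) - half, 0)
            end = min(int(gene["tss"]) + half, size)
            rows.append((gene["chrom"], start, end, float(occ),
                         float(k), "hot_promoter", gene["gene_id"]))

    # cold blocks over deserts + background over the rest
    prom_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, *_ in rows:
        prom_by_chrom.setdefault(chrom, []).append((start, end))
    cold_gain = config.mef_cold_gain if config.mode == "MEF" else 1.0
    for chrom, size in annotation.chrom_sizes.items():
        deserts = _desert_intervals(win_counts[chrom], window)
        blocked = sorted(prom_by_chrom.get(chrom, []) + deserts)
        merged: list[list[int]] = []
        for s, e in blocked:
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        for s, e in deserts:
            for ts, te in _tile_interval(s, e, config.locus_size):
                rows.append((chrom, ts, te, cold_gain, 0.0, "cold_block", ""))
        # complement of merged blocked intervals -> background tiles
        cursor = 0
        gaps = []
        for s, e in merged:
            if s > cursor:
                gaps.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < size:
            gaps.append((cursor, size))
        counts = win_counts[chrom]
        for gs, ge in gaps:
            for ts, te in _tile_interval(gs, ge, config.locus_size):
                if te - ts < 500:
                    continue
                mid_win = ((ts + te) // 2) // window
                gene_poor = mid_win < len(counts) and counts[mid_win] <= config.mef_gene_poor_max
                if config.mode == "MEF" and gene_poor:
                    rows.append((chrom, ts, te, cold_gain, 0.0, "cold_block", ""))
                else:
                    rows.append((chrom, ts, te, 1.0, config.k_background, "background", ""))

    loci = pd.DataFrame(rows, columns=["chrom", "start", "end", "occupancy", "k", "cls", "gene_id"])
    loci = loci.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
    loci.insert(0, "locus_id", [f"L{i:06d}" for i in range(len(loci))])

    cc = config.cell_cycle
    if config.rep_timing_jitter:
        loci["rep_offset"] = rng.uniform(cc.s_start, cc.s_end, size=len(loci))
    else:
        loci["rep_offset"] = 0.5 * (cc.s_start + cc.s_end)

    loci["ambient"] = config.ambient
    loci["artifact"] = False
    bg_idx = loci.index[loci["cls"] == "background"]
    if config.n_artifacts > 0 and len(bg_idx) > 0:
        pick = rng.choice(bg_idx.to_numpy(), size=min(config.n_artifacts, len(bg_idx)),
                          replace=False)
        loci.loc[pick, "ambient"] = config.ambient * config.artifact_strength
        loci.loc[pick, "artifact"] = True

    return KineticTruth(loci=loci, chrom_sizes=dict(annotation.chrom_sizes))


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def pool_fraction(t, params: PoolParams):
    """Tagged fraction of the soluble pool at time t (scalar or array)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    if params.tau == 0:
        p = (t >= params.t0).astype(float)
    else:
        p = np.where(t > params.t0, -np.expm1(-(t - params.t0) / params.tau), 0.0)
    return float(p) if p.ndim == 0 else p


def _evolve(F: np.ndarray, a: np.ndarray, b: np.ndarray, k: np.ndarray,
            pool: PoolParams) -> np.ndarray:
    """Exact elementwise solution of dF/dt = k (p(t) - F) from time a to b (a <= b)."""
    F = np.asarray(F, dtype=float)
    a = np.broadcast_to(np.asarray(a, dtype=float), F.shape).copy()
    b = np.broadcast_to(np.asarray(b, dtype=float), F.shape)
    k = np.broadcast_to(np.asarray(k, dtype=float), F.shape)
    t0, tau = pool.t0, pool.tau

    # p = 0 before t0: pure decay
    pre = np.clip(np.minimum(b, t0) - a, 0.0, None)
    F = F * np.exp(-k * pre)
    a = np.maximum(a, t0)
    seg = b > a
    if not np.any(seg):
        return F
    decay = np.exp(-k * (b - a))
    if tau == 0:
        post = 1.0 + (F - 1.0) * decay
    else:
        u_a = (a - t0) / tau
        u_b = (b - t0) / tau
        res = np.abs(1.0 - k * tau) < 1e-9
        with np.errstate(divide="ignore", invalid="ignore"):
            A = np.where(res, 0.0, k * tau / (1.0 - k * tau))
        fp_a = np.where(res, 1.0 - u_a * np.exp(-u_a), 1.0 + A * np.exp(-u_a))
        fp_b = np.where(res, 1.0 - u_b * np.exp(-u_b), 1.0 + A * np.exp(-u_b))
        post = fp_b + (F - fp_a) * decay
    return np.where(seg, post, F)


def _tagged_fraction_vec(k, rep_offset, t: float, pool: PoolParams,
                         cc: CellCycleParams | None, phase: float,
                         replicate: bool = True) -> np.ndarray:
    """Tagged fraction at time t for loci (k, rep_offset) in one cell at given phase."""
    k = np.atleast_1d(np.asarray(k, dtype=float))
    if np.any(k < 0):
        raise ValueError("k must be >= 0")
    if t < 0:
        raise ValueError("t must be >= 0")
    n = k.size
    F = np.zeros(n)
    cur = np.zeros(n)
    if replicate and cc is not None:
        if not (0 <= phase < cc.T):
            raise ValueError("phase must lie in [0, T)")
        rep_offset = np.broadcast_to(np.asarray(rep_offset, dtype=float), k.shape)
        te0 = np.mod(rep_offset - phase, cc.T)
        te0 = np.where(te0 == 0.0, cc.T, te0)  # event exactly at t=0 excluded
        j = 0
        while True:
            tj = te0 + j * cc.T
            m = tj <= t
            if not m.any():
                break
            F[m] = _evolve(F[m], cur[m], tj[m], k[m], pool)
            p_rep = pool_fraction(tj[m], pool)
            F[m] = cc.retention * F[m] + (1.0 - cc.retention) * p_rep
            cur[m] = tj[m]
            j += 1
    return _evolve(F, cur, np.full(n, float(t)), k, pool)


def tagged_fraction(locus, t: float, pool: PoolParams, cc: CellCycleParams | None,
                    phase: float = 0.0, replicate: bool = True) -> float:
    """Tagged fraction of one locus in one cell at cycle phase ``phase`` (hours).

    ``locus`` is any mapping with keys ``k`` and ``rep_offset`` (a KineticTruth
    row works). Set ``replicate=False`` (or ``cc=None``) for exchange-only
    dynamics.
    """
    k = float(locus["k"])
    ro = float(locus.get("rep_offset", 0.0)) if hasattr(locus, "get") else float(locus["rep_offset"])
    return float(_tagged_fraction_vec([k], [ro], t, pool, cc, phase, replicate)[0])


def population_signal(truth: KineticTruth, t: float, pool: PoolParams,
                      cc: CellCycleParams, n_phases: int = 256,
                      replicate: bool = True) -> pd.Series:
    """Expected tagged signal per locus: occupancy x mean tagged fraction.

    The mean is over cell-cycle phases on a midpoint grid of ``n_phases``
    points in [0, T) — the uniform-phase average over an asynchronous
    population.
    """
    if n_phases < 1:
        raise ValueError("n_phases must be >= 1")
    df = truth.loci
    k = df["k"].to_numpy(dtype=float)
    ro = df["rep_offset"].to_numpy(dtype=float)
    acc = np.zeros(len(df))
    phases = (np.arange(n_phases) + 0.5) * cc.T / n_phases
    for ph in phases:
        acc += _tagged_fraction_vec(k, ro, t, pool, cc, float(ph), replicate)
    mean_f = acc / n_phases
    return pd.Series(df["occupancy"].to_numpy() * mean_f, index=df["locus_id"], name=f"t{t:g}")


# ---------------------------------------------------------------------------
# read sampling
# ---------------------------------------------------------------------------

def sample_reads(truth: KineticTruth, signal: pd.Series, config: SimConfig,
                 rng: np.random.Generator) -> pd.DataFrame:
    """Draw aligned-read BED records from per-locus expected per-bp signal.

    Per-locus read counts are Poisson with mean depth x signal x width
    (normalized over loci); fragment starts are uniform within the locus;
    strand is random. Identical (chrom, start, strand) reads are collapsed
    with occurrence counts in the score column.
    """
    df = truth.loci
    sig = signal.reindex(df["locus_id"]).to_numpy(dtype=float)
    if np.any(~np.isfinite(sig)) or np.any(sig < 0):
        raise ValueError("signal must be finite and nonnegative for every locus")
    weights = sig * truth.widths
    total = weights.sum()
    if total <= 0:
        raise ValueError("total expected signal is zero; nothing to sample")
    lam = config.depth * weights / total
    counts = rng.poisson(lam)
    n_reads = int(counts.sum())
    if n_reads == 0:
        return pd.DataFrame(columns=hio.BED_COLUMNS)

    idx = np.repeat(np.arange(len(df)), counts)
    starts_lo = df["start"].to_numpy()[idx]
    widths = truth.widths[idx]
    span = np.maximum(widths - config.read_length, 1)
    starts = starts_lo + (rng.random(n_reads) * span).astype(np.int64)
    chrom_arr = df["chrom"].to_numpy()[idx]
    limit = np.asarray([truth.chrom_sizes[c] for c in chrom_arr]) - config.read_length
    starts = np.clip(starts, 0, limit)
    strands = np.where(rng.random(n_reads) < 0.5, "+", "-")

    reads = pd.DataFrame({"chrom": chrom_arr, "start": starts, "strand": strands})
    grouped = (reads.groupby(["chrom", "start", "strand"], sort=True, observed=True)
               .size().reset_index(name="score"))
    grouped["end"] = grouped["start"] + config.read_length
    grouped["name"] = [f"frag{i:07d}" for i in range(len(grouped))]
    grouped = grouped.sort_values(["chrom", "start", "strand"], kind="stable").reset_index(drop=True)
    return grouped[hio.BED_COLUMNS]


# ---------------------------------------------------------------------------
# end-to-end experiment
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """A full synthetic pulse-chase experiment with ground truth attached."""

    config: SimConfig
    annotation: GenomeAnnotation
    truth: KineticTruth
    signals: pd.DataFrame        # loci x time points: specific (tag) per-bp signal
    signals_total: pd.DataFrame  # specific + ambient, what reads were drawn from
    reads: dict[str, pd.DataFrame]

    @property
    def labels(self) -> list[str]:
        return [timepoint_label(t) for t in self.config.timepoints]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = {"seed": self.config.seed, "config_hash": self.config.config_hash()}
        self.annotation.to_tsv(outdir / "annotation.tsv", header=stamp)
        self.truth.to_tsv(outdir / "truth.tsv", header=stamp)
        hio.write_tsv(self.signals, outdir / "expected_signal.tsv", header=stamp, index=True)
        self.config.to_yaml(outdir / "config.yaml")
        for label, reads in self.reads.items():
            hio.write_bed(reads, outdir / f"reads_{label}.bed", header=stamp)


def simulate_experiment(config: SimConfig) -> SimResult:
    """Simulate the whole pulse-chase experiment for one cell type."""
    annotation = make_genome(config)
    truth = assign_kinetics(annotation, config)
    pool, cc = config.pool, config.cell_cycle
    specific = {}
    totals = {}
    reads = {}
    for i, t in enumerate(config.timepoints):
        label = timepoint_label(t)
        sig = population_signal(truth, t, pool, cc)
        total = sig + truth.loci.set_index("locus_id")["ambient"] * \
            truth.loci.set_index("locus_id")["occupancy"]
        specific[label] = sig
        totals[label] = total
        rng = np.random.default_rng((config.seed, 1000 + i))
        reads[label] = sample_reads(truth, total, config, rng)
    return SimResult(
        config=config,
        annotation=annotation,
        truth=truth,
        signals=pd.DataFrame(specific),
        signals_total=pd.DataFrame(totals),
        reads=reads,
    )
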