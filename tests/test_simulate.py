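import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from histodyn.simulate import (
    CellCycleParams,
    GenomeAnnotation,
    KineticTruth,
    PoolParams,
    SimConfig,
    _tagged_fraction_vec,
    assign_kinetics,
    make_genome,
    pool_fraction,
    population_signal,
    sample_reads,
    simulate_experiment,
    tagged_fraction,
)

STEP_POOL = PoolParams(t0=0.0, tau=0.0)   # p = 1 from t = 0


# ---------------------------------------------------------------------------
# make_genome
# ---------------------------------------------------------------------------

class TestMakeGenome:
    def test_no_genes(self):
        ann = make_genome(SimConfig(seed=1, n_genes=0))
        assert ann.genes.empty
        assert len(ann.chrom_sizes) == 2

    def test_determinism_byte_identical(self, tmp_path):
        paths = []
        for i in range(2):
            ann = make_genome(SimConfig(seed=7))
            p = tmp_path / f"ann{i}.tsv"
            ann.to_tsv(p)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_desert_fraction_matches_brute_force_window_count(self):
        cfg = SimConfig(seed=7)
        ann = make_genome(cfg)
        window = 100_000
        zero_windows = total_windows = 0
        for chrom, size in ann.chrom_sizes.items():
            n = size // window
            counts = np.zeros(n, dtype=int)
            tss = ann.genes.loc[ann.genes["chrom"] == chrom, "tss"].to_numpy()
            for t in tss:  # brute force, one gene at a time
                if t < n * window:
                    counts[t // window] += 1
            zero_windows += int((counts == 0).sum())
            total_windows += n
        frac = zero_windows / total_windows
        assert abs(frac - cfg.desert_fraction) < 0.06

    def test_has_desert_and_dense_region(self):
        cfg = SimConfig(seed=3)
        ann = make_genome(cfg)
        window = 100_000
        mean_density = len(ann.genes) / (ann.total_length / window)
        best = 0.0
        longest_zero_run = 0
        for chrom, size in ann.chrom_sizes.items():
            n = size // window
            counts = np.zeros(n, dtype=int)
            tss = ann.genes.loc[ann.genes["chrom"] == chrom, "tss"].to_numpy()
            np.add.at(counts, tss[tss < n * window] // window, 1)
            best = max(best, counts.max())
            run = cur = 0
            for c in counts:
                cur = cur + 1 if c == 0 else 0
                run = max(run, cur)
            longest_zero_run = max(longest_zero_run, run)
        assert longest_zero_run >= 5          # a >= 500 kb desert exists
        assert best >= 5 * mean_density       # and a dense block exists

    def test_too_small_genome_raises(self):
        with pytest.raises(ValueError, match="too small"):
            make_genome(SimConfig(seed=1, n_chroms=1, chrom_length=1_000_000,
                                  n_genes=50_000))


# ---------------------------------------------------------------------------
# assign_kinetics
# ---------------------------------------------------------------------------

class TestAssignKinetics:
    def test_k_monotone_in_expression(self, toy_annotation):
        cfg = SimConfig(seed=1)
        truth = assign_kinetics(toy_annotation, cfg)
        prom = truth.loci[truth.loci["cls"] == "hot_promoter"].set_index("gene_id")
        expr = toy_annotation.genes.set_index("gene_id")["expression"]
        # gA (8.0) < gD (9.0) -> k(gA) <= k(gD); gB (6.5) < gA (8.0)
        assert prom.loc["gB", "k"] <= prom.loc["gA", "k"] <= prom.loc["gD", "k"]
        assert set(prom.index) == set(expr[expr >= cfg.expressed_threshold].index)

    def test_mef_promoter_k_variance_smaller(self):
        cfg_es = SimConfig(seed=5, mode="ES")
        ann = make_genome(cfg_es)
        k_es = assign_kinetics(ann, cfg_es).loci.query("cls == 'hot_promoter'")["k"]
        cfg_mef = SimConfig(seed=5, mode="MEF")
        k_mef = assign_kinetics(ann, cfg_mef).loci.query("cls == 'hot_promoter'")["k"]
        assert k_mef.var() < k_es.var()

    def test_expression_k_spearman(self):
        from scipy.stats import spearmanr
        cfg = SimConfig(seed=2)
        ann = make_genome(cfg)
        truth = assign_kinetics(ann, cfg)
        prom = truth.loci[truth.loci["cls"] == "hot_promoter"].set_index("gene_id")
        expr = ann.genes.set_index("gene_id")["expression"].reindex(prom.index)
        assert spearmanr(expr, prom["k"]).statistic >= 0.9

    def test_cold_blocks_tile_deserts(self):
        cfg = SimConfig(seed=3)
        ann = make_genome(cfg)
        truth = assign_kinetics(ann, cfg)
        cold = truth.loci[truth.loci["cls"] == "cold_block"]
        assert len(cold) > 0
        assert (cold["k"] == 0).all()
        # no cold-block interval may contain a TSS
        for _, row in cold.iterrows():
            tss = ann.genes.loc[ann.genes["chrom"] == row["chrom"], "tss"]
            assert not ((tss >= row["start"]) & (tss < row["end"])).any()

    def test_mef_adds_cold_blocks(self):
        ann = make_genome(SimConfig(seed=5))
        n_es = (assign_kinetics(ann, SimConfig(seed=5, mode="ES")).loci["cls"]
                == "cold_block").sum()
        n_mef = (assign_kinetics(ann, SimConfig(seed=5, mode="MEF")).loci["cls"]
                 == "cold_block").sum()
        assert n_mef > n_es


# ---------------------------------------------------------------------------
# pool_fraction
# ---------------------------------------------------------------------------

class TestPoolFraction:
    def test_at_delay_boundary(self):
        assert pool_fraction(2.0, PoolParams(t0=2.0, tau=4.0)) == 0.0

    def test_closed_form(self):
        p = pool_fraction(6.0, PoolParams(t0=2.0, tau=4.0))
        assert p == pytest.approx(1 - np.exp(-1.0), abs=1e-12)

    def test_approaches_one_monotonically(self):
        params = PoolParams(t0=1.0, tau=2.0)
        ts = np.linspace(0, 60, 200)
        ps = pool_fraction(ts, params)
        assert np.all(np.diff(ps) >= 0)
        assert ps[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all((ps >= 0) & (ps <= 1))

    def test_negative_t_errors(self):
        with pytest.raises(ValueError):
            pool_fraction(-0.1, PoolParams())


# ---------------------------------------------------------------------------
# tagged_fraction
# ---------------------------------------------------------------------------

def euler_oracle(k: float, t: float, pool: PoolParams, cc: CellCycleParams,
                 phase: float, rep_offset: float, dt: float = 0.001) -> float:
    """Brute-force forward-Euler integration with replication resets."""
    events = []
    te = (rep_offset - phase) % cc.T
    if te == 0:
        te = cc.T
    while te <= t:
        events.append(te)
        te += cc.T
    events.append(np.inf)
    F = 0.0
    nxt = 0
    n = int(round(t / dt))
    for i in range(n):
        tt = i * dt
        F = F + dt * k * (pool_fraction(tt, pool) - F)
        if tt + dt >= events[nxt] - 1e-12 and events[nxt] <= t:
            F = cc.retention * F + (1 - cc.retention) * pool_fraction(events[nxt], pool)
            nxt += 1
    return F


class TestTaggedFraction:
    CC = CellCycleParams(T=12.0, s_start=2.0, s_end=8.0, retention=0.5)

    def test_no_pathway_gives_zero(self):
        locus = {"k": 0.0, "rep_offset": 5.0}
        # phase chosen so no replication occurs before t=3: event at (5-0) mod 12 = 5
        assert tagged_fraction(locus, 3.0, STEP_POOL, self.CC, phase=0.0) == 0.0

    def test_single_replication_update(self):
        locus = {"k": 0.0, "rep_offset": 5.0}
        # event at t=5 <= 6; F <- 0.5*0 + 0.5*1
        assert tagged_fraction(locus, 6.0, STEP_POOL, self.CC, phase=0.0) == pytest.approx(0.5)

    def test_exchange_closed_form(self):
        locus = {"k": np.log(2), "rep_offset": 5.0}
        f = tagged_fraction(locus, 1.0, STEP_POOL, None, phase=0.0)
        assert f == pytest.approx(0.5, abs=1e-12)
        f2 = tagged_fraction(locus, 2.0, STEP_POOL, None, phase=0.0)
        assert f2 == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("k", [0.1, 0.5, 1.0, 2.0])
    @pytest.mark.parametrize("t,phase", [(3.0, 1.0), (12.0, 7.3)])
    def test_matches_euler_oracle(self, k, t, phase):
        pool = PoolParams(t0=0.5, tau=1.5)
        ro = 5.0
        exact = tagged_fraction({"k": k, "rep_offset": ro}, t, pool, self.CC, phase=phase)
        approx = euler_oracle(k, t, pool, self.CC, phase, ro)
        assert exact == pytest.approx(approx, abs=1e-4)

    def test_resonant_k_equals_inverse_tau(self):
        pool = PoolParams(t0=0.0, tau=2.0)
        k = 0.5  # k * tau = 1 exactly
        exact = tagged_fraction({"k": k, "rep_offset": 5.0}, 4.0, pool, self.CC, phase=1.0)
        approx = euler_oracle(k, 4.0, pool, self.CC, 1.0, 5.0)
        assert exact == pytest.approx(approx, abs=1e-4)

    def test_negative_k_errors(self):
        with pytest.raises(ValueError):
            tagged_fraction({"k": -1.0, "rep_offset": 5.0}, 1.0, STEP_POOL, self.CC)

    @settings(max_examples=60, deadline=None)
    @given(
        k=st.floats(0.0, 4.0),
        t0=st.floats(0.0, 3.0),
        tau=st.floats(0.1, 5.0),
        retention=st.floats(0.0, 1.0),
        phase=st.floats(0.0, 11.99),
        t=st.floats(0.0, 30.0),
    )
    def test_bounds_and_monotonicity(self, k, t0, tau, retention, phase, t):
        """F(t) <= p(t) and F nondecreasing for any nondecreasing pool."""
        pool = PoolParams(t0=t0, tau=tau)
        cc = CellCycleParams(T=12.0, s_start=2.0, s_end=8.0, retention=retention)
        ts = np.linspace(0, t, 25) if t > 0 else np.array([0.0])
        fs = [tagged_fraction({"k": k, "rep_offset": 5.0}, float(ti), pool, cc, phase=phase)
              for ti in ts]
        ps = [pool_fraction(float(ti), pool) for ti in ts]
        assert all(f <= p + 1e-9 for f, p in zip(fs, ps))
        assert all(b >= a - 1e-9 for a, b in zip(fs, fs[1:]))
        assert all(0.0 <= f <= 1.0 + 1e-12 for f in fs)


# ---------------------------------------------------------------------------
# population_signal
# ---------------------------------------------------------------------------

def _truth_from_k(ks, rep_offset=5.0, occupancy=1.0) -> KineticTruth:
    n = len(ks)
    df = pd.DataFrame({
        "locus_id": [f"L{i}" for i in range(n)],
        "chrom": "chr1",
        "start": np.arange(n) * 1000,
        "end": np.arange(n) * 1000 + 1000,
        "occupancy": occupancy,
        "k": ks,
        "rep_offset": rep_offset,
        "cls": "background",
        "ambient": 0.0,
    })
    return KineticTruth(loci=df, chrom_sizes={"chr1": 10_000_000})


class TestPopulationSignal:
    CC = CellCycleParams(T=12.0, s_start=2.0, s_end=8.0, retention=0.5)

    def test_uniform_phase_arithmetic_half_cycle(self):
        truth = _truth_from_k([0.0])
        sig = population_signal(truth, 6.0, STEP_POOL, self.CC)
        assert sig.iloc[0] == pytest.approx(0.25, abs=1e-9)

    def test_uniform_phase_arithmetic_full_cycle(self):
        truth = _truth_from_k([0.0])
        sig = population_signal(truth, 12.0, STEP_POOL, self.CC)
        assert sig.iloc[0] == pytest.approx(0.5, abs=1e-9)

    def test_occupancy_scales_signal(self):
        truth = _truth_from_k([0.0], occupancy=2.5)
        sig = population_signal(truth, 12.0, STEP_POOL, self.CC)
        assert sig.iloc[0] == pytest.approx(1.25, abs=1e-8)

    def test_matches_monte_carlo_oracle(self):
        ks = [0.05, 0.3, 1.0, 2.5]
        pool = PoolParams(t0=0.5, tau=1.5)
        truth = _truth_from_k(ks)
        quad = population_signal(truth, 5.0, pool, self.CC, n_phases=512)
        rng = np.random.default_rng(0)
        n_mc = 100_000
        phases = rng.uniform(0, self.CC.T, n_mc)
        for i, k in enumerate(ks):
            # phase enters only through (rep_offset - phase) mod T
            ro = np.mod(5.0 - phases, self.CC.T)
            fs = _tagged_fraction_vec(np.full(n_mc, k), ro, 5.0, pool, self.CC, 0.0)
            se = fs.std(ddof=1) / np.sqrt(n_mc)
            assert abs(quad.iloc[i] - fs.mean()) < max(3 * se, 1e-6)

    def test_ratio_nondecreasing_in_k(self):
        """Early/late signal ratio grows with k (exchange only, step pool)."""
        ks = np.concatenate([[0.01], np.linspace(0.05, 4.0, 80)])
        truth = _truth_from_k(ks)
        s3 = population_signal(truth, 3.0, STEP_POOL, self.CC, replicate=False)
        s12 = population_signal(truth, 12.0, STEP_POOL, self.CC, replicate=False)
        ratio = (s3 / s12).to_numpy()
        assert np.all(np.diff(ratio) >= -1e-12)


# ---------------------------------------------------------------------------
# sample_reads
# ---------------------------------------------------------------------------

class TestSampleReads:
    def _setup(self):
        truth = _truth_from_k([0.5, 0.0, 1.0])
        cfg = SimConfig(seed=1, depth=50_000)
        return truth, cfg

    def test_zero_signal_locus_gets_no_reads(self):
        truth, cfg = self._setup()
        signal = pd.Series([1.0, 0.0, 1.0], index=truth.loci["locus_id"])
        reads = sample_reads(truth, signal, cfg, np.random.default_rng(0))
        dead = truth.loci.iloc[1]
        in_dead = (reads["start"] >= dead["start"]) & (reads["start"] < dead["end"])
        assert not in_dead.any()

    def test_seed_determinism(self):
        truth, cfg = self._setup()
        signal = pd.Series([1.0, 0.5, 2.0], index=truth.loci["locus_id"])
        r1 = sample_reads(truth, signal, cfg, np.random.default_rng(42))
        r2 = sample_reads(truth, signal, cfg, np.random.default_rng(42))
        pd.testing.assert_frame_equal(r1, r2)

    def test_total_occurrences_near_depth(self):
        truth, cfg = self._setup()
        signal = pd.Series([1.0, 0.5, 2.0], index=truth.loci["locus_id"])
        reads = sample_reads(truth, signal, cfg, np.random.default_rng(3))
        total = reads["score"].sum()
        assert abs(total - cfg.depth) <= 3 * np.sqrt(cfg.depth)

    def test_zero_total_signal_errors(self):
        truth, cfg = self._setup()
        signal = pd.Series(0.0, index=truth.loci["locus_id"])
        with pytest.raises(ValueError, match="zero"):
            sample_reads(truth, signal, cfg, np.random.default_rng(0))


# ---------------------------------------------------------------------------
# end-to-end determinism and the normalization-reversal property
# ---------------------------------------------------------------------------

class TestSimulateExperiment:
    def test_seeded_determinism_end_to_end(self, small_config, tmp_path):
        a = simulate_experiment(small_config)
        b = simulate_experiment(small_config)
        pd.testing.assert_frame_equal(a.signals, b.signals)
        for label in a.reads:
            pd.testing.assert_frame_equal(a.reads[label], b.reads[label])
        a.write(tmp_path / "a")
        b.write(tmp_path / "b")
        for name in ("annotation.tsv", "truth.tsv", "reads_t3.bed"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_relative_signal_reversal(self, small_config):
        """ppm-relative hot-promoter signal falls t3 -> t12 while cold rises."""
        sim = simulate_experiment(small_config)
        widths = sim.truth.widths
        rel = sim.signals_total.div(
            sim.signals_total.mul(widths, axis=0).sum(axis=0), axis=1)
        cls = sim.truth.loci.set_index("locus_id")["cls"]
        hot = rel[cls == "hot_promoter"].mean()
        cold = rel[cls == "cold_block"].mean()
        assert hot["t3"] > hot["t6"] > hot["t12"]
        assert cold["t3"] < cold["t6"] < cold["t12"]

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            SimConfig(seed=1, depth=0)

    def test_config_roundtrip(self, tmp_path, small_config):
        p = tmp_path / "cfg.yaml"
        small_config.to_yaml(p)
        back = SimConfig.from_yaml(p)
        assert back == small_config
        assert back.config_hash() == small_config.config_hash()
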