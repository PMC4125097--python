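import numpy as np
import pandas as pd
import pytest

from histodyn.coverage import CoverageTrack
from histodyn.simulate import GenomeAnnotation, SimConfig


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two small chromosomes with a handful of genes on a 20-bp-friendly grid."""
    genes = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC", "gD"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "tss": [20_000, 50_000, 80_000, 10_000],
            "strand": ["+", "-", "+", "+"],
            "expression": [8.0, 6.5, 2.0, 9.0],
        }
    )
    return GenomeAnnotation(chrom_sizes={"chr1": 100_000, "chr2": 60_000}, genes=genes)


def make_track(chrom_values: dict[str, np.ndarray], bin_size: int = 20,
               total: int = 100) -> CoverageTrack:
    sizes = {c: len(v) * bin_size for c, v in chrom_values.items()}
    return CoverageTrack(bin_size=bin_size, chrom_sizes=sizes,
                         data={c: np.asarray(v, dtype=float) for c, v in chrom_values.items()},
                         total_occurrences=total)


@pytest.fixture
def uniform_track(toy_annotation) -> CoverageTrack:
    data = {c: np.full(size // 20, 3.0) for c, size in toy_annotation.chrom_sizes.items()}
    return CoverageTrack(bin_size=20, chrom_sizes=dict(toy_annotation.chrom_sizes),
                         data=data, total_occurrences=1000)


@pytest.fixture
def small_config() -> SimConfig:
    """A fast simulation config for unit-level end-to-end checks."""
    return SimConfig(seed=11, depth=60_000, n_chroms=1, chrom_length=6_000_000,
                     n_genes=300, timepoints=(0.0, 3.0, 6.0, 12.0))
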