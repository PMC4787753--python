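import numpy as np
import pytest

from dccircuit.intervals import GeneAnnotation, GenomicInterval, PeakSet
from dccircuit.simulate import SyntheticConfig, simulate

import pandas as pd


@pytest.fixture(scope="session")
def small_config():
    """Compact four-state design used across the generator/pipeline tests."""
    return SyntheticConfig(
        n_chromosomes=1,
        chromosome_length=500_000,
        n_genes=24,
        n_tfs=8,
        targets_per_tf=2,
        replicates_per_state=3,
        planted_autoloops=2,
        n_bivalent_genes=4,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return simulate(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_annotation(genes):
    """genes: iterable of (gene_id, chrom, strand, tss)."""
    return GeneAnnotation(
        pd.DataFrame(genes, columns=["gene_id", "chrom", "strand", "tss"])
    )


def make_peaks(intervals, state="", mark=""):
    """intervals: iterable of (chrom, start, end[, score])."""
    ivs = [
        GenomicInterval(*t) if len(t) > 3 else GenomicInterval(*t, 1.0)
        for t in intervals
    ]
    return PeakSet(ivs, cell_state=state, mark=mark)
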