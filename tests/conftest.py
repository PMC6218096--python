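import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from patchwork import synthetic as syn
from patchwork.hic import ContactMatrix, make_bins


@pytest.fixture(scope="session")
def small_plan():
    return syn.BlockPlan(
        {"chr1": [("GC", 50_000, 0.52), ("AT", 25_000, 0.25), ("GC", 50_000, 0.52)]}
    )


@pytest.fixture(scope="session")
def small_genome(small_plan):
    """125 kb single-chromosome blocky genome with repeats, genes, MITEs."""
    return syn.generate_blocky_genome(small_plan, seed=11, mite_near_gene_rate=0.2)


@pytest.fixture(scope="session")
def medium_genome():
    """~3 Mb two-chromosome genome used by the Hi-C and linkage tests."""
    plan = syn.default_block_plan(n_chromosomes=2, genome_size=3_000_000, seed=2)
    return syn.generate_blocky_genome(plan, seed=2, mite_near_gene_rate=0.2)


def matrix_from_dense(dense: np.ndarray, lengths: dict[str, int], bin_size: int, balanced=False) -> ContactMatrix:
    """Wrap a dense symmetric array as a ContactMatrix for direct testing."""
    bins = make_bins(lengths, bin_size)
    assert len(bins) == dense.shape[0]
    return ContactMatrix(
        bins=bins,
        counts=sparse.csr_matrix(dense),
        bin_size=bin_size,
        balanced=balanced,
    )
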