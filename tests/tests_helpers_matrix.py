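"""Shared matrix constructors for the Hi-C and linkage tests."""

import numpy as np
from scipy import sparse

from patchwork.hic import ContactMatrix, make_bins


def matrix_from_dense(dense, lengths, bin_size, balanced=False):
    bins = make_bins(lengths, bin_size)
    assert len(bins) == dense.shape[0]
    return ContactMatrix(
        bins=bins, counts=sparse.csr_matrix(dense), bin_size=bin_size, balanced=balanced
    )


def random_symmetric_matrix(n=20, bin_size=5_000, seed=0, lam=5.0):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.poisson(lam, size=(n, n)))
    dense = upper + np.triu(upper, 1).T
    return matrix_from_dense(dense.astype(float), {"chr1": n * bin_size}, bin_size)


def block_diagonal_matrix(block_sizes, within=50.0, between=10.0, bin_size=5_000,
                          noise_rng=None):
    """Planted-TAD matrix: dense within-domain blocks over a weak background."""
    n = sum(block_sizes)
    dense = np.full((n, n), between)
    start = 0
    for b in block_sizes:
        dense[start : start + b, start : start + b] = within
        start += b
    if noise_rng is not None:
        pois = noise_rng.poisson(dense)
        dense = np.triu(pois) + np.triu(pois, 1).T
    return matrix_from_dense(dense.astype(float), {"chr1": n * bin_size}, bin_size)
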