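"""Binned Hi-C contact matrix construction and analysis.

Covers the contact-map workflow for a small repeat-blocky genome: a
k-mer-uniqueness mappability mask, MAPQ/mask pair filtering into a 5 kb
symmetric matrix, iterative (ICE) balancing, power-law distance-decay fits
per compartment, per-chromosome compartment PCA, TopDom-style TAD calling,
trans-contact centromere localization, and block-type contact summaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse, stats

from .io_formats import GenomeSequence
from .utils import overlap_length

_CODE = np.full(256, 255, dtype=np.uint64)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
_MULT = np.uint64(0x9E3779B97F4A7C15)


@dataclass
class MappabilityMask:
    """True = position excluded (no unique read of ``read_length`` starts there)."""

    masks: dict[str, np.ndarray]
    read_length: int

    @property
    def fraction_mappable(self) -> float:
        total = sum(len(m) for m in self.masks.values())
        masked = sum(int(m.sum()) for m in self.masks.values())
        return 1.0 - masked / total if total else 0.0


def mappability_mask(genome: GenomeSequence, read_length: int = 80) -> MappabilityMask:
    """Mask positions whose read-length k-mer is not unique in the genome.

    Uniqueness is strand-aware (a k-mer equal to the reverse complement of a
    k-mer elsewhere is non-unique) and computed from 64-bit polynomial
    k-mer hashes, so collisions are vanishingly unlikely rather than
    impossible. Positions too close to the chromosome end to start a full
    read are masked as well; chromosomes shorter than the read are fully
    masked.
    """
    if read_length < 20:
        raise ValueError("read_length must be >= 20")
    k = read_length
    fwd_hashes, rev_hashes, owners = [], [], []
    for chrom, seq in genome.records.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        if len(arr) < k:
            continue
        codes = _CODE[arr]
        n = len(arr) - k + 1
        hf = np.zeros(n, dtype=np.uint64)
        hr = np.zeros(n, dtype=np.uint64)
        # polynomial hash with odd multiplier; modular wraparound is the
        # intended arithmetic. N (code 255) poisons the k-mer.
        with np.errstate(over="ignore"):
            pw = np.uint64(1)
            for j in range(k - 1, -1, -1):
                hf += codes[j : j + n] * pw
                pw = pw * _MULT
            pw = np.uint64(1)
            for j in range(k):
                hr += (np.uint64(3) - codes[j : j + n]) * pw
                pw = pw * _MULT
        fwd_hashes.append(hf)
        rev_hashes.append(hr)
        owners.append((chrom, n))
    masks = {c: np.ones(len(s), dtype=bool) for c, s in genome.records.items()}
    if not fwd_hashes:
        return MappabilityMask(masks, read_length)
    hf = np.concatenate(fwd_hashes)
    hr = np.concatenate(rev_hashes)
    canon = np.minimum(hf, hr)
    _, inv, counts = np.unique(canon, return_inverse=True, return_counts=True)
    dup = counts[inv] > 1
    pos = 0
    for chrom, n in owners:
        m = masks[chrom]
        m[:n] = dup[pos : pos + n]
        # tail positions cannot start a full read and stay masked
        pos += n
    return MappabilityMask(masks, read_length)


# ---------------------------------------------------------------------------
# matrix container
# ---------------------------------------------------------------------------

@dataclass
class ContactMatrix:
    bins: pd.DataFrame  # chrom, start, end
    counts: sparse.csr_matrix  # symmetric
    bin_size: int
    balanced: bool = False
    converged: bool = True
    n_iterations: int = 0
    zero_bins: np.ndarray | None = None
    stats: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    def chrom_slice(self, chrom: str) -> slice:
        idx = np.flatnonzero((self.bins["chrom"] == chrom).to_numpy())
        return slice(int(idx[0]), int(idx[-1]) + 1)

    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def cis_dense(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slice(chrom)
        return np.asarray(self.counts[sl, sl].todense())


def make_bins(lengths: dict[str, int], bin_size: int) -> pd.DataFrame:
    rows = []
    for chrom, length in lengths.items():
        for start in range(0, length, bin_size):
            rows.append({"chrom": chrom, "start": start, "end": min(start + bin_size, length)})
    return pd.DataFrame(rows)


def build_contact_matrix(
    pairs: pd.DataFrame,
    genome: GenomeSequence | dict[str, int],
    bin_size: int = 5_000,
    mask: MappabilityMask | None = None,
    mapq_min: int = 30,
) -> ContactMatrix:
    """Bin filtered read pairs into a symmetric count matrix.

    Pairs with either end below ``mapq_min`` or on a masked position are
    excluded; the accounting (input = included + excluded) is kept in
    ``stats``. Self-bin pairs land on the diagonal once.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    lengths = genome.lengths if hasattr(genome, "lengths") else dict(genome)
    bins = make_bins(lengths, bin_size)
    offsets = {}
    off = 0
    for chrom, length in lengths.items():
        offsets[chrom] = off
        off += -(-length // bin_size)
    n = len(bins)

    keep = (pairs["mapq1"] >= mapq_min) & (pairs["mapq2"] >= mapq_min)
    if mask is not None:
        for end in ("1", "2"):
            ok = np.ones(len(pairs), dtype=bool)
            for chrom, m in mask.masks.items():
                sel = (pairs[f"chrom{end}"] == chrom).to_numpy()
                if sel.any():
                    p = pairs.loc[sel, f"pos{end}"].to_numpy()
                    ok[sel] = ~m[np.clip(p, 0, len(m) - 1)]
            keep &= ok
    sub = pairs[keep]
    i = sub["chrom1"].map(offsets).to_numpy() + sub["pos1"].to_numpy() // bin_size
    j = sub["chrom2"].map(offsets).to_numpy() + sub["pos2"].to_numpy() // bin_size
    lo, hi = np.minimum(i, j), np.maximum(i, j)
    upper = sparse.coo_matrix(
        (np.ones(len(sub)), (lo, hi)), shape=(n, n)
    ).tocsr()
    counts = upper + upper.T - sparse.diags(upper.diagonal())
    return ContactMatrix(
        bins=bins,
        counts=counts.tocsr(),
        bin_size=bin_size,
        stats={"n_input": int(len(pairs)), "n_included": int(len(sub)),
               "n_excluded": int(len(pairs) - len(sub))},
    )


# ---------------------------------------------------------------------------
# ICE balancing
# ---------------------------------------------------------------------------

def ice_normalize(
    matrix: ContactMatrix, tol: float = 1e-5, max_iter: int = 200
) -> ContactMatrix:
    """Iterative correction: equalize marginals by square-root scaling.

    Each iteration divides rows and columns by the square root of their
    mean-normalized marginal; convergence is declared when the coefficient
    of variation of the nonzero marginals drops below ``tol``. Bins with
    zero coverage are dropped from the iteration and re-inserted as zeros.
    """
    W = matrix.counts.astype(float).tocsr(copy=True)
    marg = np.asarray(W.sum(axis=1)).ravel()
    nz = marg > 0
    if not nz.any():
        raise ValueError("matrix has no nonzero rows")
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        marg = np.asarray(W.sum(axis=1)).ravel()
        m_nz = marg[nz]
        cv = m_nz.std() / m_nz.mean()
        if cv < tol:
            converged = True
            break
        s = np.ones_like(marg)
        s[nz] = m_nz / m_nz.mean()
        d = sparse.diags(1.0 / np.sqrt(s))
        W = d @ W @ d
    return ContactMatrix(
        bins=matrix.bins,
        counts=W.tocsr(),
        bin_size=matrix.bin_size,
        balanced=True,
        converged=converged,
        n_iterations=it,
        zero_bins=~nz,
        stats=dict(matrix.stats),
    )


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

@dataclass
class DecayFit:
    label: str
    alpha: float
    intercept: float
    r_squared: float
    fit_range: tuple[float, float]
    n_distance_bins: int


def _bins_within_regions(bins: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    sel = np.zeros(len(bins), dtype=bool)
    for _, r in regions.iterrows():
        sel |= (
            (bins["chrom"] == r["chrom"])
            & (bins["start"] >= r["start"])
            & (bins["end"] <= r["end"])
        ).to_numpy()
    return sel


def fit_distance_decay(
    matrix: ContactMatrix,
    regions: pd.DataFrame | None = None,
    min_sep: int | None = None,
    max_sep: int = 1_000_000,
    min_region_len: int = 100_000,
    growth: float = 1.2,
    label: str = "all",
) -> DecayFit:
    """Power-law exponent of contact frequency versus genomic distance.

    Mean contact count per log-spaced distance bin (1.2x growth, default
    range [2 x bin size, 1 Mb]) is regressed on distance in log-log space;
    alpha is the slope. When ``regions`` is given, only regions longer than
    ``min_region_len`` contribute, and only bins fully inside them.
    """
    if min_sep is None:
        min_sep = 2 * matrix.bin_size
    if regions is not None:
        regions = regions[(regions["end"] - regions["start"]) > min_region_len]
        if not len(regions):
            raise ValueError("no regions pass the length filter")
        sel = _bins_within_regions(matrix.bins, regions)
    else:
        sel = np.ones(len(matrix.bins), dtype=bool)
    edges = [float(min_sep)]
    while edges[-1] < max_sep:
        edges.append(edges[-1] * growth)
    edges = np.array(edges)
    mids = (matrix.bins["start"].to_numpy() + matrix.bins["end"].to_numpy()) / 2.0
    all_d, all_c, all_w = [], [], []
    for chrom in matrix.chroms():
        sl = matrix.chrom_slice(chrom)
        idx = np.flatnonzero(sel[sl])
        if len(idx) < 2:
            continue
        M = matrix.cis_dense(chrom)
        sub = M[np.ix_(idx, idx)]
        m = mids[sl][idx]
        dist = np.abs(m[:, None] - m[None, :])
        iu = np.triu_indices(len(idx), k=1)
        d = dist[iu]
        c = sub[iu]
        which = np.searchsorted(edges, d, side="right") - 1
        ok = (which >= 0) & (which < len(edges) - 1)
        all_d.append(d[ok])
        all_c.append(c[ok])
        all_w.append(which[ok])
    if not all_d:
        raise ValueError("fewer than 3 nonempty distance bins; cannot fit decay")
    d = np.concatenate(all_d)
    c = np.concatenate(all_c)
    which = np.concatenate(all_w)
    nb = len(edges) - 1
    npairs = np.bincount(which, minlength=nb).astype(float)
    mean = np.zeros(nb)
    np.add.at(mean, which, c)
    mean = np.divide(mean, npairs, out=np.zeros(nb), where=npairs > 0)
    good = (npairs > 0) & (mean > 0)
    if good.sum() < 3:
        raise ValueError("fewer than 3 nonempty distance bins; cannot fit decay")
    # self-consistent bin representatives: with the true alpha, the point
    # ((mean d^alpha)^(1/alpha), mean c) lies exactly on the power law, so an
    # exact power-law input is recovered to machine precision
    alpha = -1.0
    res = None
    for _ in range(50):
        a = min(-1e-3, alpha)
        rep = np.zeros(nb)
        np.add.at(rep, which, d**a)
        rep = np.divide(rep, npairs, out=np.ones(nb), where=npairs > 0) ** (1.0 / a)
        res = stats.linregress(np.log10(rep[good]), np.log10(mean[good]))
        if abs(res.slope - alpha) < 1e-12:
            alpha = float(res.slope)
            break
        alpha = float(res.slope)
    return DecayFit(
        label=label,
        alpha=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        fit_range=(float(min_sep), float(max_sep)),
        n_distance_bins=int(good.sum()),
    )


# ---------------------------------------------------------------------------
# compartment PCA
# ---------------------------------------------------------------------------

def bin_at_fraction(bins: pd.DataFrame, blocks: pd.DataFrame) -> np.ndarray:
    """Fraction of each bin covered by AT-rich blocks."""
    at = blocks[blocks["kind"] == "AT"]
    out = np.zeros(len(bins))
    for chrom in bins["chrom"].unique():
        m = (bins["chrom"] == chrom).to_numpy()
        sub = at[at["chrom"] == chrom]
        if not len(sub):
            continue
        bs = bins.loc[m, "start"].to_numpy()
        be = bins.loc[m, "end"].to_numpy()
        cov = np.array(
            [
                overlap_length(s, e, sub["start"].to_numpy(), sub["end"].to_numpy()).sum()
                for s, e in zip(bs, be)
            ],
            dtype=float,
        )
        out[m] = cov / (be - bs)
    return out


def compartment_pca(
    matrix: ContactMatrix,
    blocks: pd.DataFrame,
    use_oe: bool = True,
    min_informative: int = 10,
) -> pd.DataFrame:
    """Per-chromosome PC1/PC2 of the (observed/expected, correlated) cis map.

    PCA runs on each chromosome's cis submatrix after an
    observed-over-expected-by-distance transform and Pearson correlation
    (``use_oe=False`` skips both and decomposes raw balanced counts). PC1
    sign is oriented so its correlation with per-bin AT fraction is
    positive; the flip is recorded per chromosome in the ``flipped`` column.
    """
    from sklearn.decomposition import PCA

    at_frac = bin_at_fraction(matrix.bins, blocks)
    out = matrix.bins.copy()
    out["pc1"] = np.nan
    out["pc2"] = np.nan
    out["informative"] = False
    out["flipped"] = False
    for chrom in matrix.chroms():
        sl = matrix.chrom_slice(chrom)
        M = matrix.cis_dense(chrom)
        marg = M.sum(axis=1)
        info = marg > 0
        if info.sum() < min_informative:
            continue
        sub = M[np.ix_(np.flatnonzero(info), np.flatnonzero(info))]
        if use_oe:
            n = len(sub)
            pos = np.arange(n)
            dmat = np.abs(pos[:, None] - pos[None, :])
            diag_mean = np.array([sub.diagonal(d).mean() for d in range(n)])
            expected = diag_mean[dmat]
            with np.errstate(invalid="ignore", divide="ignore"):
                oe = np.where(expected > 0, sub / expected, 0.0)
                C = np.corrcoef(oe)
            C[~np.isfinite(C)] = 0.0
        else:
            C = sub.astype(float)
        scores = PCA(n_components=2, svd_solver="full").fit_transform(C)
        pc1 = np.full(M.shape[0], np.nan)
        pc2 = np.full(M.shape[0], np.nan)
        pc1[info] = scores[:, 0]
        pc2[info] = scores[:, 1]
        af = at_frac[sl][info]
        flipped = False
        if np.std(af) > 0 and np.std(scores[:, 0]) > 0:
            r = np.corrcoef(scores[:, 0], af)[0, 1]
            if r < 0:
                pc1 = -pc1
                flipped = True
        rows = np.arange(sl.start, sl.stop)
        out.loc[rows, "pc1"] = pc1
        out.loc[rows, "pc2"] = pc2
        out.loc[rows, "informative"] = info
        out.loc[rows, "flipped"] = flipped
    return out


# ---------------------------------------------------------------------------
# TAD calling
# ---------------------------------------------------------------------------

def _diamond_cells(M: np.ndarray, b: int, w: int) -> np.ndarray:
    """Cells between the w bins left of boundary b|b+1 and the w bins right."""
    n = M.shape[0]
    left = np.arange(max(0, b - w + 1), b + 1)
    right = np.arange(b + 1, min(n, b + 1 + w))
    if not len(left) or not len(right):
        return np.array([])
    return M[np.ix_(left, right)].ravel()


def call_tads(
    matrix: ContactMatrix,
    window_bins: int = 5,
    min_bins: int = 5,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """TopDom-style TAD calling from the balanced matrix.

    Per-bin diamond means are computed across each candidate boundary;
    boundaries are local minima of this signal that pass a one-sided rank
    test (within-domain diamonds exceed the boundary diamond) with
    Benjamini-Hochberg control across candidates at ``alpha`` (0.01 keeps
    long uniform domains intact while a 5:1 contrast is still detected). Domains shorter than
    ``min_bins`` are merged into the neighbour with the stronger shared
    contact; all-zero runs are labelled gaps.
    """
    w = window_bins
    rows = []
    for chrom in matrix.chroms():
        sl = matrix.chrom_slice(chrom)
        M = matrix.cis_dense(chrom)
        n = M.shape[0]
        starts = matrix.bins["start"].to_numpy()[sl]
        ends = matrix.bins["end"].to_numpy()[sl]
        zero = M.sum(axis=1) == 0
        # maximal non-gap runs
        runs = []
        i = 0
        while i < n:
            j = i
            while j < n and zero[j] == zero[i]:
                j += 1
            runs.append((i, j, bool(zero[i])))
            i = j
        k = 0
        for ri, rj, is_gap in runs:
            if is_gap:
                rows.append(
                    {"chrom": chrom, "start": int(starts[ri]), "end": int(ends[rj - 1]),
                     "label": "gap", "tad_id": ""}
                )
                continue
            for s_bin, e_bin in _domains_in_run(M[ri:rj, ri:rj], w, min_bins, alpha):
                k += 1
                rows.append(
                    {
                        "chrom": chrom,
                        "start": int(starts[ri + s_bin]),
                        "end": int(ends[ri + e_bin]),
                        "label": "TAD",
                        "tad_id": f"{chrom}.{k}",
                    }
                )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "label", "tad_id"])


def _domains_in_run(M: np.ndarray, w: int, min_bins: int, alpha: float) -> list[tuple[int, int]]:
    n = M.shape[0]
    if n < 2 * w:
        return [(0, n - 1)]
    signal = np.array([_diamond_cells(M, b, w).mean() for b in range(n - 1)])
    cand = []
    for b in range(n - 1):
        lo, hi = max(0, b - w), min(n - 1, b + w + 1)
        window = signal[lo:hi]
        if signal[b] <= window.min() and window.max() > window.min():
            cand.append(b)
    # collapse adjacent plateau candidates to their centre
    merged = []
    for b in cand:
        if merged and b - merged[-1][-1] == 1:
            merged[-1].append(b)
        else:
            merged.append([b])
    cand = [grp[len(grp) // 2] for grp in merged]
    # rank-test screen against within-domain diamonds
    pvals = []
    for b in cand:
        boundary = _diamond_cells(M, b, w)
        within = np.concatenate(
            [_diamond_cells(M, b - w, w) if b - w >= 0 else np.array([]),
             _diamond_cells(M, b + w, w) if b + w < n - 1 else np.array([])]
        )
        if not len(within) or not len(boundary):
            pvals.append(0.0)
            continue
        if np.all(within == within[0]) and np.all(boundary == boundary[0]) and within[0] == boundary[0]:
            pvals.append(1.0)
            continue
        pvals.append(
            float(stats.mannwhitneyu(within, boundary, alternative="greater").pvalue)
        )
    if cand:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        prev = 1.0
        for rank, oi in enumerate(order[::-1]):
            r = m - rank
            prev = min(prev, pvals[oi] * m / r)
            adj[oi] = prev
        cand = [b for b, pa in zip(cand, adj) if pa < alpha]
    boundaries = sorted(cand)
    domains = []
    prev = 0
    for b in boundaries:
        domains.append((prev, b))
        prev = b + 1
    domains.append((prev, n - 1))
    # merge undersized domains into the neighbour with the stronger contact
    changed = True
    while changed and len(domains) > 1:
        changed = False
        for i, (s, e) in enumerate(domains):
            if e - s + 1 < min_bins:
                left_link = M[s : e + 1, max(0, s - w) : s].mean() if i > 0 else -1
                right_link = (
                    M[s : e + 1, e + 1 : min(n, e + 1 + w)].mean()
                    if i < len(domains) - 1
                    else -1
                )
                if left_link >= right_link and i > 0:
                    domains[i - 1] = (domains[i - 1][0], e)
                else:
                    domains[i + 1] = (s, domains[i + 1][1])
                domains.pop(i)
                changed = True
                break
    return domains


# ---------------------------------------------------------------------------
# centromeres
# ---------------------------------------------------------------------------

def detect_centromeres(
    matrix: ContactMatrix,
    max_iter: int = 50,
    n_perm: int = 200,
    seed: int = 0,
    window: int = 1,
) -> pd.DataFrame:
    """Locate centromere bins from mutually-maximal trans contacts.

    Iterates: each chromosome's candidate bin maximizes its summed trans
    contacts (+-``window`` bins) with the other chromosomes' current
    candidates, until a fixed point. Significance of each final score comes
    from permuting the partner bins; ties break to the lowest coordinate.
    """
    chroms = matrix.chroms()
    if len(chroms) < 2:
        raise ValueError("need >= 2 chromosomes for trans-contact centromere calling")
    dense = np.asarray(matrix.counts.todense())
    slices = {c: matrix.chrom_slice(c) for c in chroms}
    for c in chroms:
        sl = slices[c]
        dense[sl, sl] = 0.0
    if dense.sum() == 0:
        raise ValueError("no trans contacts")
    rng = np.random.default_rng(seed)

    def score_rows(c: str, cand: dict[str, int]) -> np.ndarray:
        sl = slices[c]
        s = np.zeros(sl.stop - sl.start)
        for o in chroms:
            if o == c:
                continue
            lo = max(slices[o].start, cand[o] - window)
            hi = min(slices[o].stop, cand[o] + window + 1)
            s += dense[sl, lo:hi].sum(axis=1)
        return s

    cand = {}
    for c in chroms:
        sl = slices[c]
        # seed from the strongest single trans contact: centromere-centromere
        # cells are point-like, so a row-sum start can miss their basin
        cand[c] = sl.start + int(np.argmax(dense[sl].max(axis=1)))
    for _ in range(max_iter):
        new = {}
        for c in chroms:
            s = score_rows(c, cand)
            new[c] = slices[c].start + int(np.argmax(s))
        if new == cand:
            break
        cand = new
    rows = []
    for c in chroms:
        sl = slices[c]
        obs = score_rows(c, cand)[cand[c] - sl.start]
        null = []
        for _ in range(n_perm):
            rand = {
                o: int(rng.integers(slices[o].start, slices[o].stop)) for o in chroms
            }
            rand[c] = cand[c]
            null.append(score_rows(c, rand).max())
        p = (1 + sum(v >= obs for v in null)) / (n_perm + 1)
        b = matrix.bins.iloc[cand[c]]
        rows.append(
            {
                "chrom": c,
                "start": int(b["start"]),
                "end": int(b["end"]),
                "score": float(obs),
                "pvalue": float(p),
                "confident": p < 0.05,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# block-type summaries
# ---------------------------------------------------------------------------

def bin_block_kind(bins: pd.DataFrame, blocks: pd.DataFrame) -> np.ndarray:
    """Majority-base block type per bin ('AT' or 'GC')."""
    frac = bin_at_fraction(bins, blocks)
    return np.where(frac > 0.5, "AT", "GC")


def block_contact_summary(matrix: ContactMatrix, blocks: pd.DataFrame) -> pd.DataFrame:
    """Observed vs expected contact shares by block-type pair, cis and trans.

    Expected shares assume random pairing: the product of genomic base
    fractions (2fg for the mixed pair).
    """
    kind = bin_block_kind(matrix.bins, blocks)
    is_at = kind == "AT"
    chrom_codes = pd.factorize(matrix.bins["chrom"])[0]
    coo = sparse.triu(matrix.counts).tocoo()
    same_chrom = chrom_codes[coo.row] == chrom_codes[coo.col]
    at_i, at_j = is_at[coo.row], is_at[coo.col]
    pair_type = np.where(at_i & at_j, "AT-AT", np.where(~at_i & ~at_j, "GC-GC", "AT-GC"))
    f_at = (
        (blocks.loc[blocks["kind"] == "AT", "end"] - blocks.loc[blocks["kind"] == "AT", "start"]).sum()
        / (blocks["end"] - blocks["start"]).sum()
    )
    expected = {"AT-AT": f_at**2, "AT-GC": 2 * f_at * (1 - f_at), "GC-GC": (1 - f_at) ** 2}
    rows = []
    for scope, m in (("cis", same_chrom), ("trans", ~same_chrom)):
        total = coo.data[m].sum()
        for pt in ("AT-AT", "AT-GC", "GC-GC"):
            obs = coo.data[m & (pair_type == pt)].sum()
            rows.append(
                {
                    "scope": scope,
                    "pair_type": pt,
                    "observed_share": obs / total if total else np.nan,
                    "expected_share": expected[pt],
                }
            )
    return pd.DataFrame(rows)


def tads_per_block(tads: pd.DataFrame, blocks: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd TADs per block by block kind (>50%-overlap assignment)."""
    tad_rows = tads[tads["label"] == "TAD"]
    counts = {i: 0 for i in blocks.index}
    assigned_len = {"AT": [], "GC": []}
    for _, t in tad_rows.iterrows():
        tlen = t["end"] - t["start"]
        sub = blocks[blocks["chrom"] == t["chrom"]]
        ov = overlap_length(t["start"], t["end"], sub["start"].to_numpy(), sub["end"].to_numpy())
        best = np.flatnonzero(ov > 0.5 * tlen)
        if len(best):
            bi = sub.index[best[0]]
            counts[bi] += 1
            assigned_len[blocks.loc[bi, "kind"]].append(tlen)
    rows = []
    for kind in ("AT", "GC"):
        idx = blocks.index[blocks["kind"] == kind]
        c = np.array([counts[i] for i in idx], dtype=float)
        rows.append(
            {
                "kind": kind,
                "mean_tads_per_block": c.mean() if len(c) else np.nan,
                "sd_tads_per_block": c.std(ddof=1) if len(c) > 1 else np.nan,
                "mean_tad_length": float(np.mean(assigned_len[kind])) if assigned_len[kind] else np.nan,
                "n_blocks": len(c),
            }
        )
    return pd.DataFrame(rows)
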