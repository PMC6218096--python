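"""Statistics linking genome architecture to gene expression.

TAD co-regulation (OLS with TAD membership against a covariate-only null,
compared by AIC), gene-set contact enrichment against permutation nulls in
fixed genomic-distance categories, a Mantel control test relating AT-block
contact and shared-repeat-family distances, AT-block proximity odds ratios
at 5 kb, MITE enrichment near differentially expressed genes, and 6mA
compartment summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .io_formats import GenomeSequence
from .utils import interval_distance, overlap_length

DISTANCE_BINS = (
    ("cis_0_5kb", 0, 5_000),
    ("cis_5_20kb", 5_000, 20_000),
    ("cis_20_200kb", 20_000, 200_000),
    ("cis_200kb_1Mb", 200_000, 1_000_000),
    ("cis_ge_1Mb", 1_000_000, np.inf),
    ("trans", None, None),
)


# ---------------------------------------------------------------------------
# TAD co-regulation
# ---------------------------------------------------------------------------

@dataclass
class TadModelResult:
    table: pd.DataFrame  # per-TAD estimate, CI, p, BH-adjusted p, significant
    delta_aic: float
    aic_full: float
    aic_null: float
    covariates: list[str]
    n_genes: int
    dropped_tads: list[str] = field(default_factory=list)


def _gene_density(genes: pd.DataFrame, radius: int = 5_000) -> np.ndarray:
    """Number of other genes whose span comes within ``radius`` bp."""
    out = np.zeros(len(genes), dtype=float)
    for chrom, grp in genes.groupby("chrom", sort=False):
        s = grp["start"].to_numpy()
        e = grp["end"].to_numpy()
        for local_i, gi in enumerate(grp.index):
            gap = np.maximum(s - e[local_i], s[local_i] - e)
            out[genes.index.get_loc(gi)] = int((gap <= radius).sum()) - 1
    return out


def _te_within(genes: pd.DataFrame, repeats: pd.DataFrame, radius: int = 500) -> np.ndarray:
    out = np.zeros(len(genes), dtype=float)
    if repeats is None or not len(repeats):
        return out
    for chrom, grp in genes.groupby("chrom", sort=False):
        sub = repeats[repeats["chrom"] == chrom]
        if not len(sub):
            continue
        d = interval_distance(
            grp["start"].to_numpy(), grp["end"].to_numpy(),
            sub["start"].to_numpy(), sub["end"].to_numpy(),
        )
        out[[genes.index.get_loc(i) for i in grp.index]] = (d <= radius).astype(float)
    return out


def tad_coregulation_model(
    expr: pd.DataFrame,
    tads: pd.DataFrame | None = None,
    repeats: pd.DataFrame | None = None,
    genome: GenomeSequence | None = None,
    fdr: float = 0.01,
    min_genes_per_tad: int = 2,
) -> TadModelResult:
    """Does TAD membership predict expression change beyond local covariates?

    Fits log2 fold-change on TAD membership plus gene density (genes within
    5 kb), gene GC fraction (when a genome is supplied) and a TE-within-500 bp
    indicator (when repeats are supplied); the null drops TAD membership.
    ``delta_aic = AIC(null) - AIC(full)`` so positive values favour
    TAD-level co-regulation. Per-TAD adjusted means are tested against zero
    with Benjamini-Hochberg control at ``fdr``.
    """
    df = expr.copy()
    if "tad_id" not in df.columns or df["tad_id"].isna().all():
        if tads is None:
            raise ValueError("need either an expr tad_id column or a TAD table")
        mid = (df["start"] + df["end"]) // 2
        tad_id = np.full(len(df), "", dtype=object)
        for _, t in tads[tads.get("label", "TAD") != "gap"].iterrows():
            m = (df["chrom"] == t["chrom"]) & (mid >= t["start"]) & (mid < t["end"])
            tad_id[m.to_numpy()] = t["tad_id"]
        df["tad_id"] = tad_id
    df["tad_id"] = df["tad_id"].fillna("")
    sizes = df[df["tad_id"] != ""].groupby("tad_id").size()
    good_tads = sizes[sizes >= min_genes_per_tad].index
    dropped = sorted(set(sizes.index) - set(good_tads))
    df = df[df["tad_id"].isin(good_tads)].reset_index(drop=True)
    if df["tad_id"].nunique() < 2:
        raise ValueError(
            "TAD co-regulation model is unidentifiable with fewer than two "
            "populated TADs"
        )
    y = df["lfc"].to_numpy(dtype=float)
    cov_cols: dict[str, np.ndarray] = {}
    cov_cols["gene_density"] = _gene_density(df)
    if genome is not None:
        from .utils import gc_fraction

        cov_cols["gc_fraction"] = np.array(
            [gc_fraction(genome[r["chrom"]][r["start"] : r["end"]]) for _, r in df.iterrows()]
        )
    if repeats is not None and len(repeats):
        cov_cols["te_within_500bp"] = _te_within(df, repeats)
    X_cov = np.column_stack([v - v.mean() for v in cov_cols.values()]) if cov_cols else np.empty((len(df), 0))
    tad_codes, tad_levels = pd.factorize(df["tad_id"])
    dummies = np.eye(len(tad_levels))[tad_codes]
    full = sm.OLS(y, np.column_stack([dummies, X_cov])).fit()
    null = sm.OLS(y, np.column_stack([np.ones(len(df)), X_cov])).fit()
    est = full.params[: len(tad_levels)]
    ci = full.conf_int()[: len(tad_levels)]
    pv = np.array(
        [float(full.t_test(np.eye(full.params.shape[0])[i]).pvalue) for i in range(len(tad_levels))]
    )
    p_adj = sm.stats.multipletests(pv, method="fdr_bh")[1] if len(pv) else pv
    table = pd.DataFrame(
        {
            "tad_id": tad_levels,
            "estimate": est,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
            "pvalue": pv,
            "p_adj": p_adj,
            "significant": p_adj < fdr,
            "n_genes": sizes.loc[tad_levels].to_numpy(),
        }
    )
    return TadModelResult(
        table=table,
        delta_aic=float(null.aic - full.aic),
        aic_full=float(full.aic),
        aic_null=float(null.aic),
        covariates=list(cov_cols),
        n_genes=len(df),
        dropped_tads=list(dropped),
    )


# ---------------------------------------------------------------------------
# gene-set contact enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per distance bin: observed, expected, envelope, excess, p
    n_permutations: int
    set_size: int
    which: str


def _pair_categories(mid: np.ndarray, chrom_code: np.ndarray, idx: np.ndarray):
    ii, jj = np.triu_indices(len(idx), k=1)
    a, b = idx[ii], idx[jj]
    same = chrom_code[a] == chrom_code[b]
    d = np.abs(mid[a] - mid[b])
    cat = np.full(len(a), len(DISTANCE_BINS) - 1, dtype=int)  # trans
    for ci, (_, lo, hi) in enumerate(DISTANCE_BINS[:-1]):
        cat[same & (d >= lo) & (d < hi)] = ci
    cat[~same] = len(DISTANCE_BINS) - 1
    return a, b, cat


def gene_set_contact_enrichment(
    matrix,
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    which: str = "top",
    fraction: float = 0.05,
    n_perm: int = 1_000,
    seed: int = 0,
    gene_set: pd.Index | None = None,
) -> EnrichmentResult:
    """Do genes of an expression extreme contact each other more than chance?

    The observed statistic is the mean contact count over all pairs of bins
    holding set members, split into the fixed distance categories; the null
    re-draws ``n_perm`` uniform same-size gene sets. ``which='bottom'``
    excludes zero-expression genes before taking the lowest ``fraction``.
    An explicit ``gene_set`` (gene_ids) overrides the expression ranking.
    """
    rng = np.random.default_rng(seed)
    df = genes.merge(expr[["gene_id", "mean_expr"]], on="gene_id", how="inner")
    eligible = df[df["mean_expr"] > 0] if which == "bottom" else df
    eligible = eligible.reset_index(drop=True)
    if gene_set is not None:
        set_idx = np.flatnonzero(eligible["gene_id"].isin(gene_set).to_numpy())
        k = len(set_idx)
    else:
        k = int(round(fraction * len(eligible)))
        if k < 10:
            raise ValueError("fraction selects fewer than 10 genes")
        order = np.argsort(eligible["mean_expr"].to_numpy())
        set_idx = order[-k:] if which == "top" else order[:k]
    dense = np.asarray(matrix.counts.todense())
    # bin of each gene midpoint
    mid = ((eligible["start"] + eligible["end"]) // 2).to_numpy()
    chrom_code = pd.factorize(eligible["chrom"])[0]
    offsets = {}
    for chrom in matrix.chroms():
        offsets[chrom] = matrix.chrom_slice(chrom).start
    gbin = np.array(
        [offsets[c] + m // matrix.bin_size for c, m in zip(eligible["chrom"], mid)]
    )

    def set_stat(idx: np.ndarray) -> np.ndarray:
        a, b, cat = _pair_categories(mid, chrom_code, idx)
        vals = dense[gbin[a], gbin[b]]
        out = np.full(len(DISTANCE_BINS), np.nan)
        for ci in range(len(DISTANCE_BINS)):
            m = cat == ci
            if m.any():
                out[ci] = vals[m].mean()
        return out

    obs = set_stat(np.asarray(set_idx))
    null = np.empty((n_perm, len(DISTANCE_BINS)))
    for p in range(n_perm):
        null[p] = set_stat(rng.choice(len(eligible), size=k, replace=False))
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        # distance bins with no eligible pairs are all-NaN and stay undefined
        _warnings.simplefilter("ignore", RuntimeWarning)
        expected = np.nanmean(null, axis=0)
        lo = np.nanpercentile(null, 2.5, axis=0)
        hi = np.nanpercentile(null, 97.5, axis=0)
        excess = (obs - expected) / obs
        pvals = np.array(
            [
                (1 + np.sum(null[~np.isnan(null[:, ci]), ci] >= obs[ci])) / (np.sum(~np.isnan(null[:, ci])) + 1)
                if np.isfinite(obs[ci])
                else np.nan
                for ci in range(len(DISTANCE_BINS))
            ]
        )
    table = pd.DataFrame(
        {
            "distance_bin": [b[0] for b in DISTANCE_BINS],
            "observed": obs,
            "expected": expected,
            "envelope_low": lo,
            "envelope_high": hi,
            "excess": excess,
            "pvalue": pvals,
            "defined": np.isfinite(obs),
        }
    )
    return EnrichmentResult(table=table, n_permutations=n_perm, set_size=k, which=which)


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    pvalue: float
    n_permutations: int
    defined: bool = True
    exact: bool = False


def mantel_test(
    d1: np.ndarray,
    d2: np.ndarray,
    n_perm: int = 9_999,
    seed: int = 0,
    exact: bool = False,
) -> MantelResult:
    """Two-sided Mantel permutation test between square distance matrices.

    ``exact=True`` (or ``n_perm >= n!``) enumerates all row/column
    permutations and returns the exact permutation p-value (identity
    included); otherwise a Monte-Carlo p with the add-one correction.
    """
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    v1, v2 = d1[iu], d2[iu]
    if v1.std() == 0 or v2.std() == 0:
        return MantelResult(float("nan"), float("nan"), 0, defined=False)
    r_obs = float(np.corrcoef(v1, v2)[0, 1])
    if exact or (n <= 8 and n_perm >= math.factorial(n)):
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            p = np.asarray(perm)
            rp = float(np.corrcoef(d1[np.ix_(p, p)][iu], v2)[0, 1])
            count += abs(rp) >= abs(r_obs) - 1e-12
            total += 1
        return MantelResult(r_obs, count / total, total, exact=True)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        rp = float(np.corrcoef(d1[np.ix_(p, p)][iu], v2)[0, 1])
        count += abs(rp) >= abs(r_obs) - 1e-12
    return MantelResult(r_obs, (1 + count) / (n_perm + 1), n_perm)


def mantel_repeat_contacts(
    at_blocks: pd.DataFrame,
    matrix,
    repeats: pd.DataFrame,
    n_perm: int = 9_999,
    seed: int = 0,
    transform: str = "inv1p",
    agg: str = "mean",
    min_region_len: int = 15_000,
) -> MantelResult:
    """Mantel control: AT-block contact distance vs shared-repeat-family distance.

    Contact distance is ``1/(1 + contacts)`` between the blocks' bins
    (monotone alternatives: ``neglog`` for ``-log1p(contacts)``); repeat
    distance is one minus the Jaccard similarity of the blocks'
    repeat-family sets. ``agg='mean'`` (default) averages contacts over the
    two blocks' bin pairs so that block size cancels, and regions shorter
    than ``min_region_len`` (~3 bins) are dropped: one-bin regions couple
    sampling noise in the contact estimate to family-set size and would
    bias the null toward positive correlation. Absence of correlation
    supports contacts not being a repeat-mismapping artefact.
    """
    blocks = at_blocks[at_blocks.get("kind", "AT") == "AT"]
    blocks = blocks[(blocks["end"] - blocks["start"]) >= min_region_len].reset_index(drop=True)
    if len(blocks) < 4:
        raise ValueError("need at least 4 AT-rich regions for a Mantel test")
    bins = matrix.bins
    bin_mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) // 2
    region_bins = []
    fam_sets = []
    for _, b in blocks.iterrows():
        m = (bins["chrom"] == b["chrom"]).to_numpy() & (bin_mid >= b["start"]) & (bin_mid < b["end"])
        region_bins.append(np.flatnonzero(m))
        sub = repeats[(repeats["chrom"] == b["chrom"])]
        ov = overlap_length(b["start"], b["end"], sub["start"].to_numpy(), sub["end"].to_numpy())
        fam_sets.append(set(sub.loc[ov > 0, "family"]))
    n = len(blocks)
    dense = np.asarray(matrix.counts.todense())
    contact = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if len(region_bins[i]) and len(region_bins[j]):
                sub = dense[np.ix_(region_bins[i], region_bins[j])]
                contact[i, j] = contact[j, i] = sub.mean() if agg == "mean" else sub.sum()
    if transform == "inv1p":
        d1 = 1.0 / (1.0 + contact)
    elif transform == "neglog":
        d1 = -np.log1p(contact)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(d1, 0.0)
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b_ = fam_sets[i], fam_sets[j]
            jac = len(a & b_) / len(a | b_) if (a | b_) else 0.0
            d2[i, j] = d2[j, i] = 1.0 - jac
    return mantel_test(d1, d2, n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# proximity odds ratio
# ---------------------------------------------------------------------------

@dataclass
class OddsRatioResult:
    gene_class: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    counts: dict
    corrected: bool = False


def proximity_odds_ratio(
    genes: pd.DataFrame,
    class_label: str | pd.Series | np.ndarray,
    blocks: pd.DataFrame,
    max_dist: int = 5_000,
) -> OddsRatioResult:
    """Are genes of a class over-represented within 5 kb of AT-rich blocks?

    Cross-classifies genes (within ``max_dist`` of an AT block, 0 if
    overlapping, vs not) against the binary class and fits a
    single-predictor logistic regression; with all cells nonzero the fitted
    odds ratio equals the 2x2 cross-product ratio. Empty cells fall back to
    the Haldane-Anscombe +0.5 correction, flagged.
    """
    if isinstance(class_label, str):
        is_class = genes["class_labels"].astype(str).str.contains(class_label).to_numpy() if "class_labels" in genes else genes[class_label].astype(bool).to_numpy()
        name = class_label
    else:
        is_class = np.asarray(class_label, dtype=bool)
        name = "class"
    at = blocks[blocks["kind"] == "AT"]
    near = np.zeros(len(genes), dtype=bool)
    for chrom in genes["chrom"].unique():
        m = (genes["chrom"] == chrom).to_numpy()
        sub = at[at["chrom"] == chrom]
        d = interval_distance(
            genes.loc[m, "start"].to_numpy(), genes.loc[m, "end"].to_numpy(),
            sub["start"].to_numpy(), sub["end"].to_numpy(),
        )
        near[m] = d <= max_dist
    a = int(np.sum(is_class & near))
    b = int(np.sum(is_class & ~near))
    c = int(np.sum(~is_class & near))
    d_ = int(np.sum(~is_class & ~near))
    counts = {"class_near": a, "class_far": b, "other_near": c, "other_far": d_}
    if min(a, b, c, d_) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d_ + 0.5
        or_ = (a2 * d2) / (b2 * c2)
        se = math.sqrt(1 / a2 + 1 / b2 + 1 / c2 + 1 / d2)
        return OddsRatioResult(
            name, or_, or_ * math.exp(-1.96 * se), or_ * math.exp(1.96 * se),
            counts, corrected=True,
        )
    X = sm.add_constant(near.astype(float))
    fit = sm.GLM(is_class.astype(float), X, family=sm.families.Binomial()).fit(tol=1e-10)
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    return OddsRatioResult(
        name,
        math.exp(beta),
        math.exp(beta - 1.96 * se),
        math.exp(beta + 1.96 * se),
        counts,
    )


# ---------------------------------------------------------------------------
# MITE enrichment
# ---------------------------------------------------------------------------

@dataclass
class MiteEnrichment:
    family_table: pd.DataFrame  # per family: mean copies near DE vs others, fold
    frac_de: float  # fraction of DE genes with any MITE within window
    frac_other: float
    pooled_fold: float  # fold of pooled mean copy counts
    profile: pd.DataFrame  # per (quantile, position bin): fold
    n_excluded_no_strand: int = 0


def mite_enrichment(
    mites: pd.DataFrame,
    genes: pd.DataFrame,
    expr: pd.DataFrame,
    window: int = 2_000,
    top_fraction: float = 0.20,
    quantiles: int = 4,
    position_bins: np.ndarray | None = None,
) -> MiteEnrichment:
    """MITE copy enrichment near the most up-regulated genes.

    Per family, the mean number of copies within ``window`` of each gene's
    coding span is compared between the ``top_fraction`` most up-regulated
    genes and all others. The positional profile counts copies by signed
    TSS-relative position (negative = upstream, minus-strand genes flipped)
    per differential-expression quantile, as a fold over the genes outside
    that quantile.
    """
    if position_bins is None:
        position_bins = np.arange(-2_000, 2_001, 500)
    df = genes.merge(expr[["gene_id", "lfc"]], on="gene_id", how="inner")
    no_strand = ~df["strand"].isin(["+", "-"])
    n_excluded = int(no_strand.sum())
    df = df[~no_strand].reset_index(drop=True)
    n_top = max(1, int(round(top_fraction * len(df))))
    order = np.argsort(-df["lfc"].to_numpy())
    is_de = np.zeros(len(df), dtype=bool)
    is_de[order[:n_top]] = True

    families = sorted(mites["family"].unique()) if len(mites) else []
    copy_counts = {fam: np.zeros(len(df)) for fam in families}
    for chrom, grp in df.groupby("chrom", sort=False):
        msub = mites[mites["chrom"] == chrom]
        if not len(msub):
            continue
        gs = grp["start"].to_numpy()
        ge = grp["end"].to_numpy()
        for fam, fsub in msub.groupby("family"):
            ms, me = fsub["start"].to_numpy(), fsub["end"].to_numpy()
            for li, gi in enumerate(grp.index):
                gap = np.maximum(ms - ge[li], gs[li] - me)
                copy_counts[fam][gi] = int((gap <= window).sum())
    fam_rows = []
    for fam in families:
        cc = copy_counts[fam]
        mean_de = cc[is_de].mean() if is_de.any() else np.nan
        mean_other = cc[~is_de].mean() if (~is_de).any() else np.nan
        fam_rows.append(
            {
                "family": fam,
                "mean_copies_de": mean_de,
                "mean_copies_other": mean_other,
                "fold": mean_de / mean_other if mean_other else np.nan,
            }
        )
    total = np.sum([copy_counts[f] for f in families], axis=0) if families else np.zeros(len(df))
    any_near = total > 0
    frac_de = float(any_near[is_de].mean()) if is_de.any() else float("nan")
    frac_other = float(any_near[~is_de].mean()) if (~is_de).any() else float("nan")
    pooled_de = total[is_de].mean() if is_de.any() else np.nan
    pooled_other = total[~is_de].mean() if (~is_de).any() else np.nan
    pooled_fold = float(pooled_de / pooled_other) if pooled_other else float("nan")

    # positional profile, strand-flipped TSS-relative
    tss = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    # rank-based quantiles (1 = most up-regulated); robust to ties/tiny n
    order = np.argsort(-df["lfc"].to_numpy(), kind="stable")
    qlab_arr = np.empty(len(df), dtype=int)
    qlab_arr[order] = np.arange(len(df)) * quantiles // max(len(df), 1) + 1
    qlab = pd.Series(qlab_arr, index=df.index)
    prof_rows = []
    mite_mid = ((mites["start"] + mites["end"]) // 2).to_numpy() if len(mites) else np.array([])
    positions_per_gene: list[np.ndarray] = []
    for gi in range(len(df)):
        msub = mites[mites["chrom"] == df.loc[gi, "chrom"]]
        if not len(msub):
            positions_per_gene.append(np.array([]))
            continue
        mm = ((msub["start"] + msub["end"]) // 2).to_numpy()
        rel = mm - tss[gi]
        if df.loc[gi, "strand"] == "-":
            rel = -rel
        rel = rel[(rel >= position_bins[0]) & (rel < position_bins[-1])]
        positions_per_gene.append(rel)
    for q in range(1, quantiles + 1):
        in_q = (qlab == q).to_numpy()
        for bi in range(len(position_bins) - 1):
            lo, hi = position_bins[bi], position_bins[bi + 1]

            def dens(mask: np.ndarray) -> float:
                if not mask.any():
                    return float("nan")
                tot = sum(
                    int(((positions_per_gene[g] >= lo) & (positions_per_gene[g] < hi)).sum())
                    for g in np.flatnonzero(mask)
                )
                return tot / mask.sum()

            dq, drest = dens(in_q), dens(~in_q)
            prof_rows.append(
                {
                    "quantile": q,
                    "pos_low": int(lo),
                    "pos_high": int(hi),
                    "density_quantile": dq,
                    "density_rest": drest,
                    "fold": dq / drest if drest else np.nan,
                }
            )
    return MiteEnrichment(
        family_table=pd.DataFrame(fam_rows, columns=["family", "mean_copies_de", "mean_copies_other", "fold"]),
        frac_de=frac_de,
        frac_other=frac_other,
        pooled_fold=pooled_fold,
        profile=pd.DataFrame(prof_rows),
        n_excluded_no_strand=n_excluded,
    )


# ---------------------------------------------------------------------------
# 6mA summary
# ---------------------------------------------------------------------------

def methylation_summary(
    mod_calls: pd.DataFrame,
    blocks: pd.DataFrame,
    genes: pd.DataFrame | None,
    genome: GenomeSequence,
    modqv_min: float = 20,
) -> dict:
    """Fraction of adenines 6mA-modified per compartment, with ApX contexts.

    Calls below ``modqv_min`` are removed. Adenine denominators count A on
    both strands (A on +, T on -) per compartment; the ApX context reads the
    base 3' of the called adenine on its own strand. A call that does not
    sit on an adenine after strand resolution is an error.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    passing = mod_calls[mod_calls["modqv"] >= modqv_min]
    denom = {"AT": 0, "GC": 0}
    for chrom, seq in genome.records.items():
        arr = np.frombuffer(seq.encode(), dtype="S1")
        is_a = (arr == b"A") | (arr == b"T")
        sub = blocks[blocks["chrom"] == chrom]
        for _, b in sub.iterrows():
            denom[b["kind"]] += int(is_a[b["start"] : b["end"]].sum())
    counts = {"AT": 0, "GC": 0}
    context_rows = []
    coding = {"AT": 0, "GC": 0}
    for chrom, calls in passing.groupby("chrom", sort=False):
        seq = genome[chrom]
        arr = np.frombuffer(seq.encode(), dtype="S1")
        pos = calls["pos"].to_numpy(dtype=int)
        plus = (calls["strand"] == "+").to_numpy()
        base = arr[pos]
        bad = np.where(plus, base != b"A", base != b"T")
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"modification call at {chrom}:{pos[i]}({calls['strand'].iloc[i]}) "
                "is not on an adenine"
            )
        # compartment lookup via sorted AT intervals
        sub = blocks[(blocks["chrom"] == chrom) & (blocks["kind"] == "AT")].sort_values("start")
        in_at = np.zeros(len(pos), dtype=bool)
        if len(sub):
            idx = np.searchsorted(sub["start"].to_numpy(), pos, side="right") - 1
            valid = idx >= 0
            in_at[valid] = pos[valid] < sub["end"].to_numpy()[idx[valid]]
        # 3' neighbour on the call's strand
        nxt_pos = np.where(plus, pos + 1, pos - 1)
        ok_nxt = (nxt_pos >= 0) & (nxt_pos < len(arr))
        nxt = np.full(len(pos), "N", dtype=object)
        raw = arr[np.clip(nxt_pos, 0, len(arr) - 1)].astype(str)
        nxt[ok_nxt] = np.where(plus, raw, [comp[c] for c in raw])[ok_nxt]
        in_gene = np.zeros(len(pos), dtype=bool)
        if genes is not None and len(genes):
            gsub = genes[genes["chrom"] == chrom].sort_values("start")
            if len(gsub):
                gi = np.searchsorted(gsub["start"].to_numpy(), pos, side="right") - 1
                valid = gi >= 0
                in_gene[valid] = pos[valid] < gsub["end"].to_numpy()[gi[valid]]
        for k in range(len(pos)):
            kind = "AT" if in_at[k] else "GC"
            counts[kind] += 1
            context_rows.append(
                {"compartment": kind, "context": f"Ap{nxt[k]}", "coding": bool(in_gene[k])}
            )
            if in_gene[k]:
                coding[kind] += 1
    ctx = pd.DataFrame(context_rows, columns=["compartment", "context", "coding"])
    frac = {
        k: counts[k] / denom[k] if denom[k] else float("nan") for k in ("AT", "GC")
    }
    breakdown = (
        ctx.groupby(["compartment", "context"]).size().rename("n").reset_index()
        if len(ctx)
        else pd.DataFrame(columns=["compartment", "context", "n"])
    )
    return {
        "fraction_modified": frac,
        "n_calls_passing": {k: counts[k] for k in counts},
        "n_adenines": denom,
        "context_breakdown": breakdown,
        "coding_calls": coding,
    }
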