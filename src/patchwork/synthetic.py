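"""Synthetic genomes, repeats, Hi-C pairs, expression and 6mA calls.

Generates data with the statistical structure of a repeat-blocky fungal
genome: alternating AT-rich (peak GC ~25%, mean length ~25.7 kb) and
GC-rich (peak GC ~52%, mean length ~55.3 kb) blocks, RIP-mutated nested
repeats in the AT blocks, MITEs and genes in the GC blocks, Hi-C contacts
with compartment-specific power-law distance decay and same-type affinity,
and expression log2 fold-changes with TAD-level shared effects.

Every generator is deterministic given its seed; stages draw from named
substreams of one global seed so each is independently reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, PAIR_COLUMNS
from .utils import array_to_seq, random_sequence, seq_to_array, substream

# ---------------------------------------------------------------------------
# parameter types
# ---------------------------------------------------------------------------


@dataclass
class BlockPlan:
    """Ordered (kind, length, gc_target) blocks per chromosome."""

    blocks: dict[str, list[tuple[str, int, float]]]

    def __post_init__(self):
        for chrom, blist in self.blocks.items():
            for kind, length, gc in blist:
                if kind not in ("AT", "GC"):
                    raise ValueError(f"{chrom}: block kind must be AT or GC, got {kind!r}")
                if length <= 0:
                    raise ValueError(f"{chrom}: block length must be positive")
                if not 0 < gc < 1:
                    raise ValueError(f"{chrom}: gc_target must be in (0,1)")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: sum(b[1] for b in bl) for c, bl in self.blocks.items()}

    def total_size(self) -> int:
        return sum(self.chrom_lengths.values())


@dataclass
class RipParams:
    """Per-site probability that a RIP-target cytosine is mutated C->T."""

    rate: float
    target_dinucleotide: str = "CA"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.rate <= 1:
            raise ValueError("rate must be in [0,1]")
        if len(self.target_dinucleotide) != 2 or "C" not in self.target_dinucleotide:
            raise ValueError("target dinucleotide must be two letters containing C")


@dataclass
class HiCSimParams:
    n_pairs: int
    alpha_within_AT: float = -0.55
    alpha_within_GC: float = -1.29
    same_type_affinity: float = 1.0
    trans_fraction: float = 0.1
    centromere_boost: float = 1.0
    centromere_window: int = 20_000
    min_distance: int = 1_000
    contaminant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_pairs < 0:
            raise ValueError("n_pairs must be >= 0")
        if not 0 <= self.trans_fraction <= 1:
            raise ValueError("trans_fraction must be in [0,1]")
        if self.same_type_affinity < 0 or self.centromere_boost < 0:
            raise ValueError("affinities must be >= 0")


@dataclass
class ExpressionSimParams:
    tad_effect_sd: float = 0.5
    residual_sd: float = 1.0
    n_de_fraction: float = 0.0
    de_boost: float = 4.0
    mite_fold: float = 1.0
    mite_window: int = 2_000
    seed: int = 0

    def __post_init__(self):
        if self.tad_effect_sd < 0 or self.residual_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.n_de_fraction <= 1:
            raise ValueError("n_de_fraction must be in [0,1]")


@dataclass
class RepeatFamily:
    name: str
    repeat_class: str  # "Class I" | "Class II" | "MITE" | "unknown"
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------------
# block plans
# ---------------------------------------------------------------------------

def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def default_block_plan(
    n_chromosomes: int = 7,
    genome_size: int = 35_000_000,
    at_mean: float = 25_700,
    at_sd: float = 25_500,
    gc_mean: float = 55_300,
    gc_sd: float = 74_700,
    at_gc: float = 0.25,
    gc_gc: float = 0.52,
    min_block: int = 5_000,
    seed: int = 0,
) -> BlockPlan:
    """Alternating AT/GC block plan with log-normal block lengths.

    Defaults match the composition of the genome the package models: block
    length means/sds of 25.7 (25.5) kb for AT-rich and 55.3 (74.7) kb for
    GC-rich blocks, with peak GC 25% and 52%. Log-normal lengths are used
    because only a mean and sd are reported and lengths must stay positive.
    """
    rng = substream(seed, "block-plan")
    at_mu, at_sig = _lognormal_params(at_mean, at_sd)
    gc_mu, gc_sig = _lognormal_params(gc_mean, gc_sd)
    chrom_target = genome_size // n_chromosomes
    blocks: dict[str, list[tuple[str, int, float]]] = {}
    for ci in range(n_chromosomes):
        blist: list[tuple[str, int, float]] = []
        total = 0
        kind = "GC"  # chromosomes begin and end gene-rich (subtelomeres)
        while total < chrom_target:
            if kind == "AT":
                length = int(max(min_block, rng.lognormal(at_mu, at_sig)))
                gc = at_gc
            else:
                length = int(max(min_block, rng.lognormal(gc_mu, gc_sig)))
                gc = gc_gc
            blist.append((kind, length, gc))
            total += length
            kind = "AT" if kind == "GC" else "GC"
        # trim the final block to land exactly on the chromosome target
        kind_l, len_l, gc_l = blist[-1]
        excess = total - chrom_target
        if len_l - excess >= min_block:
            blist[-1] = (kind_l, len_l - excess, gc_l)
        else:
            blist.pop()
            kind_p, len_p, gc_p = blist[-1]
            blist[-1] = (kind_p, len_p + (len_l - excess), gc_p)
        if blist[-1][0] == "AT":  # end gene-rich: fold trailing AT into last GC
            _, l, _ = blist.pop()
            kind_p, len_p, gc_p = blist[-1]
            blist[-1] = (kind_p, len_p + l, gc_p)
        blocks[f"chr{ci + 1}"] = blist
    return BlockPlan(blocks)


def default_repeat_library(
    seed: int = 0,
    n_class1: int = 3,
    n_class2: int = 3,
    n_mite: int = 3,
    ref_gc: float = 0.32,
) -> list[RepeatFamily]:
    """Reference sequences for long transposons (AT-biased) and MITEs.

    Long-element references are drawn AT-biased so that RIP-mutated copies
    settle near the AT-block composition target; MITEs are short and
    GC-balanced, matching elements that escape RIP.
    """
    rng = substream(seed, "repeat-library")
    fams: list[RepeatFamily] = []
    for i in range(n_class1):
        length = int(rng.integers(4_000, 7_000))
        fams.append(RepeatFamily(f"EFT-R{i + 1}", "Class I", random_sequence(rng, length, ref_gc)))
    for i in range(n_class2):
        length = int(rng.integers(2_000, 4_000))
        fams.append(RepeatFamily(f"EFT-D{i + 1}", "Class II", random_sequence(rng, length, ref_gc)))
    for i in range(n_mite):
        length = int(rng.integers(200, 450))
        fams.append(RepeatFamily(f"EFT-M{i + 1}", "MITE", random_sequence(rng, length, 0.50)))
    return fams


# ---------------------------------------------------------------------------
# RIP
# ---------------------------------------------------------------------------

def apply_rip(sequence: str, params: RipParams, rng: np.random.Generator | None = None) -> str:
    """Mutate C->T at the target dinucleotide (and G->A in its reverse
    complement context) each independently with probability ``params.rate``.

    Targets are located on the input sequence, then mutated simultaneously,
    so one mutation cannot create or destroy another target in the same
    pass. Length and all A/T bases are preserved.
    """
    if not sequence:
        return sequence
    if rng is None:
        rng = substream(params.seed, "rip")
    arr = seq_to_array(sequence).copy()
    target = params.target_dinucleotide.upper()
    c_at = target.index("C")
    # reverse complement of the target, scanned on the forward strand
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = comp[target[1]] + comp[target[0]]
    g_at = 1 - c_at
    b0, b1 = target[0].encode(), target[1].encode()
    r0, r1 = rc[0].encode(), rc[1].encode()
    fwd = np.flatnonzero((arr[:-1] == b0) & (arr[1:] == b1)) + c_at
    rev = np.flatnonzero((arr[:-1] == r0) & (arr[1:] == r1)) + g_at
    if params.rate > 0:
        hit_f = fwd[rng.random(len(fwd)) < params.rate]
        hit_r = rev[rng.random(len(rev)) < params.rate]
        arr[hit_f] = b"T"
        arr[hit_r] = b"A"
    return array_to_seq(arr)


# ---------------------------------------------------------------------------
# nested repeat insertion
# ---------------------------------------------------------------------------

class NestedInsertionResult(NamedTuple):
    sequence: str
    repeats: pd.DataFrame  # start, end, family, repeat_class, copy_id, fragment_index
    interruptions: pd.DataFrame  # interrupted_family/copy, interrupting_family/copy


def insert_nested_repeats(
    block_sequence: str,
    family_library: list[RepeatFamily],
    n_insertions: int,
    seed: int | np.random.Generator = 0,
    rip: RipParams | None = None,
    copy_prefix: str = "cp",
    _copies: list[tuple[RepeatFamily, str]] | None = None,
) -> NestedInsertionResult:
    """Splice repeat copies into a sequence at random points, one at a time.

    An insertion that lands strictly inside an existing copy splits it into
    linked fragments sharing one copy identifier; the split event is logged
    as an interruption (interrupted family -> interrupting family). Fragment
    indices are assigned in genomic order after all insertions.
    """
    rng = seed if isinstance(seed, np.random.Generator) else substream(seed, "nesting")
    if _copies is None:
        if n_insertions > 0 and not family_library:
            raise ValueError("family library is empty")
        _copies = []
        for _ in range(n_insertions):
            fam = family_library[rng.integers(len(family_library))]
            seq = fam.sequence
            if rip is not None:
                seq = apply_rip(seq, rip, rng)
            _copies.append((fam, seq))
    if n_insertions > 0:
        for fam, seq in _copies:
            if len(seq) > len(block_sequence):
                raise ValueError(
                    f"insertion of {fam.name} ({len(seq)} bp) longer than block "
                    f"({len(block_sequence)} bp)"
                )
    frags: list[dict] = []  # mutable fragment records
    inter_rows: list[dict] = []
    seq_now = block_sequence
    for ci, (fam, cseq) in enumerate(_copies):
        copy_id = f"{copy_prefix}{ci + 1:05d}"
        m = len(cseq)
        boundaries = {f["start"] for f in frags} | {f["end"] for f in frags}
        # avoid fragment boundaries so each insertion either strictly splits
        # one fragment or lands in unannotated sequence
        for _ in range(1000):
            p = int(rng.integers(0, len(seq_now) + 1)) if seq_now else 0
            if p not in boundaries:
                break
        split_target = None
        for f in frags:
            if f["start"] < p < f["end"]:
                split_target = f
                break
        new_frags = []
        for f in frags:
            if f["end"] <= p:
                new_frags.append(f)
            elif f["start"] >= p:
                f["start"] += m
                f["end"] += m
                new_frags.append(f)
            else:  # strictly split
                left = dict(f, end=p)
                right = dict(f, start=p + m, end=f["end"] + m)
                new_frags.extend([left, right])
        frags = new_frags
        if split_target is not None:
            inter_rows.append(
                {
                    "interrupted_family": split_target["family"],
                    "interrupted_copy": split_target["copy_id"],
                    "interrupting_family": fam.name,
                    "interrupting_copy": copy_id,
                }
            )
        frags.append(
            {
                "start": p,
                "end": p + m,
                "family": fam.name,
                "repeat_class": fam.repeat_class,
                "copy_id": copy_id,
            }
        )
        seq_now = seq_now[:p] + cseq + seq_now[p:]
    rep = pd.DataFrame(
        frags, columns=["start", "end", "family", "repeat_class", "copy_id"]
    )
    if len(rep):
        rep = rep.sort_values(["copy_id", "start"], kind="stable")
        rep["fragment_index"] = rep.groupby("copy_id").cumcount()
        rep = rep.sort_values("start", kind="stable").reset_index(drop=True)
    else:
        rep["fragment_index"] = pd.Series(dtype=int)
    inter = pd.DataFrame(
        inter_rows,
        columns=[
            "interrupted_family",
            "interrupted_copy",
            "interrupting_family",
            "interrupting_copy",
        ],
    )
    return NestedInsertionResult(seq_now, rep, inter)


# ---------------------------------------------------------------------------
# genome generator
# ---------------------------------------------------------------------------

class GenomeResult(NamedTuple):
    genome: GenomeSequence
    blocks: pd.DataFrame  # chrom, start, end, kind, gc_target, realized_gc
    repeats: pd.DataFrame  # chrom, start, end, strand, family, repeat_class, copy_id, fragment_index
    genes: pd.DataFrame  # gene_id, chrom, start, end, strand
    centromeres: pd.DataFrame  # chrom, pos
    interruptions: pd.DataFrame


def _build_at_block(
    length: int,
    library: list[RepeatFamily],
    rng: np.random.Generator,
    gc_target: float,
    repeat_fill: float,
    rip_rate_range: tuple[float, float],
    copy_prefix: str,
) -> NestedInsertionResult:
    """One AT-rich block: RIP-mutated nested repeat copies in tuned filler.

    Filler GC is solved so the whole block lands on the composition target
    regardless of how much GC the RIPped copies retain.
    """
    long_fams = [f for f in library if f.repeat_class != "MITE"]
    copies: list[tuple[RepeatFamily, str]] = []
    rep_len = 0
    budget = repeat_fill * length
    while long_fams:
        fam = long_fams[int(rng.integers(len(long_fams)))]
        if rep_len + fam.length > budget:
            break
        rate = float(rng.uniform(*rip_rate_range))
        copies.append((fam, apply_rip(fam.sequence, RipParams(rate=rate), rng)))
        rep_len += fam.length
    filler_len = length - rep_len
    gc_in_copies = sum(c.count("G") + c.count("C") for _, c in copies)
    want_gc = int(round(gc_target * length))
    filler_gc = min(0.95, max(0.05, (want_gc - gc_in_copies) / max(filler_len, 1)))
    filler = random_sequence(rng, filler_len, filler_gc)
    return insert_nested_repeats(
        filler, library, 0, seed=rng, _copies=copies, copy_prefix=copy_prefix
    )


def generate_blocky_genome(
    plan: BlockPlan,
    seed: int = 0,
    library: list[RepeatFamily] | None = None,
    repeat_fill: float = 0.85,
    rip_rate_range: tuple[float, float] = (0.4, 0.9),
    gene_length_mean: float = 1_400,
    gene_spacing_mean: float = 1_100,
    mite_near_gene_rate: float = 0.07,
    min_block: int = 1_000,
) -> GenomeResult:
    """Emit a genome tiling the plan exactly, with annotations.

    AT blocks carry nested, RIP-mutated long-repeat copies (~``repeat_fill``
    of their bases); GC blocks carry genes and, upstream of a random subset
    of genes, single MITE copies. All coordinates are 0-based half-open.
    Deterministic given ``seed``.
    """
    for chrom, blist in plan.blocks.items():
        for kind, length, _ in blist:
            if length < min_block:
                raise ValueError(
                    f"{chrom}: {kind} block of {length} bp is shorter than the "
                    f"minimum placeable feature ({min_block} bp); rejecting plan"
                )
    rng = substream(seed, "genome")
    if library is None:
        library = default_repeat_library(seed)
    mite_fams = [f for f in library if f.repeat_class == "MITE"]
    records: dict[str, str] = {}
    block_rows, rep_rows, gene_rows, cent_rows, inter_frames = [], [], [], [], []
    copy_counter = 0
    gene_counter = 0
    for chrom, blist in plan.blocks.items():
        pieces: list[str] = []
        offset = 0
        for kind, length, gc_target in blist:
            if kind == "AT":
                res = _build_at_block(
                    length, library, rng, gc_target, repeat_fill, rip_rate_range,
                    copy_prefix=f"{chrom}_b{len(block_rows)}_",
                )
                copy_counter += res.repeats["copy_id"].nunique() if len(res.repeats) else 0
                seq = res.sequence
                rep = res.repeats.copy()
                if len(rep):
                    rep["start"] += offset
                    rep["end"] += offset
                    rep["chrom"] = chrom
                    rep["strand"] = "+"
                    rep_rows.append(rep)
                if len(res.interruptions):
                    inter_frames.append(res.interruptions)
            else:
                seq = random_sequence(rng, length, gc_target)
                mite_local: list[tuple[int, RepeatFamily, str]] = []
                pos = 0
                while True:
                    gap = int(max(200, rng.normal(gene_spacing_mean, gene_spacing_mean / 4)))
                    glen = int(max(600, rng.normal(gene_length_mean, gene_length_mean / 4)))
                    gene_start = pos + gap
                    gene_end = gene_start + glen
                    if gene_end + 200 > length:
                        break
                    strand = "+" if rng.random() < 0.5 else "-"
                    gene_counter += 1
                    gene_rows.append(
                        {
                            "gene_id": f"g{gene_counter:05d}",
                            "chrom": chrom,
                            "start": offset + gene_start,
                            "end": offset + gene_end,
                            "strand": strand,
                        }
                    )
                    pos = gene_end
                    # optionally drop one MITE just upstream of the TSS
                    if mite_fams and rng.random() < mite_near_gene_rate:
                        fam = mite_fams[int(rng.integers(len(mite_fams)))]
                        d = int(rng.integers(150, 1_000))
                        if strand == "+":
                            m_start = gene_start - d - fam.length
                            if m_start > gene_start - gap + 50:
                                mite_local.append((m_start, fam, strand))
                        else:
                            m_start = gene_end + d
                            if m_start + fam.length + 200 < length:
                                mite_local.append((m_start, fam, strand))
                                pos = m_start + fam.length
                for m_start, fam, strand in mite_local:
                    seq = seq[:m_start] + fam.sequence + seq[m_start + fam.length :]
                    rep_rows.append(
                        pd.DataFrame(
                            [
                                {
                                    "chrom": chrom,
                                    "start": offset + m_start,
                                    "end": offset + m_start + fam.length,
                                    "strand": strand,
                                    "family": fam.name,
                                    "repeat_class": "MITE",
                                    "copy_id": f"{chrom}_m{copy_counter}",
                                    "fragment_index": 0,
                                }
                            ]
                        )
                    )
                    copy_counter += 1
            arr = seq_to_array(seq)
            n_gc = int(np.count_nonzero((arr == b"G") | (arr == b"C")))
            block_rows.append(
                {
                    "chrom": chrom,
                    "start": offset,
                    "end": offset + length,
                    "kind": kind,
                    "gc_target": gc_target,
                    "realized_gc": n_gc / length,
                }
            )
            pieces.append(seq)
            offset += length
        records[chrom] = "".join(pieces)
        cent_rows.append({"chrom": chrom, "pos": offset // 2})
    genome = GenomeSequence(records)
    blocks = pd.DataFrame(block_rows)
    repeats = (
        pd.concat(rep_rows, ignore_index=True)
        if rep_rows
        else pd.DataFrame(
            columns=[
                "chrom", "start", "end", "strand", "family",
                "repeat_class", "copy_id", "fragment_index",
            ]
        )
    )
    repeats = repeats.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    genes = pd.DataFrame(
        gene_rows, columns=["gene_id", "chrom", "start", "end", "strand"]
    )
    inter = (
        pd.concat(inter_frames, ignore_index=True)
        if inter_frames
        else pd.DataFrame(
            columns=[
                "interrupted_family", "interrupted_copy",
                "interrupting_family", "interrupting_copy",
            ]
        )
    )
    return GenomeResult(genome, blocks, repeats, genes, pd.DataFrame(cent_rows), inter)


# ---------------------------------------------------------------------------
# Hi-C pair simulation
# ---------------------------------------------------------------------------

def _sample_power_law(
    rng: np.random.Generator, alpha: float, s_min: float, s_max: np.ndarray
) -> np.ndarray:
    """Inverse-CDF draws from p(s) ~ s^alpha on [s_min, s_max]."""
    u = rng.random(len(s_max))
    if abs(alpha + 1.0) < 1e-9:
        return s_min * (s_max / s_min) ** u
    a1 = alpha + 1.0
    return (s_min**a1 + u * (s_max**a1 - s_min**a1)) ** (1.0 / a1)


def simulate_hic_pairs(
    blocks: pd.DataFrame,
    genome: GenomeSequence | dict[str, int],
    params: HiCSimParams,
    centromeres: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Positional Hi-C read pairs with compartment-aware decay and affinity.

    Cis distances follow ``s^alpha`` with the exponent of the anchor's block
    type; same-type pairs are up-weighted by ``same_type_affinity``; trans
    pairs between centromere windows by ``centromere_boost``. MAPQ is 60
    (a contaminant fraction at MAPQ 0 can be requested to exercise filters).
    """
    rng = substream(params.seed, "hic-pairs")
    lengths = genome.lengths if hasattr(genome, "lengths") else dict(genome)
    chroms = list(lengths)
    L = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_index = {c: i for i, c in enumerate(chroms)}
    # per-chromosome block boundary lookup: kind of any position
    bstarts, bkinds = {}, {}
    for c in chroms:
        sub = blocks[blocks["chrom"] == c].sort_values("start")
        bstarts[c] = sub["start"].to_numpy()
        bkinds[c] = (sub["kind"] == "AT").to_numpy()
    cent_pos = {}
    if centromeres is not None:
        cent_pos = dict(zip(centromeres["chrom"], centromeres["pos"]))

    def kind_of(ci: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        for c in chroms:
            m = ci == chrom_index[c]
            if m.any():
                idx = np.searchsorted(bstarts[c], pos[m], side="right") - 1
                out[m] = bkinds[c][np.clip(idx, 0, len(bkinds[c]) - 1)]
        return out  # True = AT

    n_trans = int(round(params.n_pairs * params.trans_fraction))
    if len(chroms) < 2:
        n_trans = 0  # trans pairs are impossible on a one-chromosome genome
    n_cis = params.n_pairs - n_trans
    out_c1, out_p1, out_c2, out_p2 = [], [], [], []

    # --- cis ---
    need = n_cis
    w_max = max(params.same_type_affinity, 1.0)
    while need > 0:
        batch = max(1000, int(need * 1.6))
        ci = rng.choice(len(chroms), size=batch, p=L / L.sum())
        p1 = np.floor(rng.random(batch) * L[ci]).astype(np.int64)
        at1 = kind_of(ci, p1)
        alpha = np.where(at1, params.alpha_within_AT, params.alpha_within_GC)
        s = np.empty(batch)
        for a in np.unique(alpha):
            m = alpha == a
            s[m] = _sample_power_law(rng, a, params.min_distance, L[ci[m]] - 1)
        s = np.round(s).astype(np.int64)
        direction = np.where(rng.random(batch) < 0.5, 1, -1)
        p2 = p1 + direction * s
        ok = (p2 >= 0) & (p2 < L[ci])
        at2 = kind_of(ci, np.clip(p2, 0, None))
        w = np.where(at1 == at2, params.same_type_affinity, 1.0)
        ok &= rng.random(batch) < (w / w_max)
        sel = np.flatnonzero(ok)[: min(need, int(ok.sum()))]
        out_c1.append(ci[sel])
        out_p1.append(p1[sel])
        out_c2.append(ci[sel])
        out_p2.append(p2[sel])
        need -= len(sel)

    # --- trans ---
    need = n_trans
    wc_max = max(params.same_type_affinity, 1.0) * max(params.centromere_boost, 1.0)
    while need > 0:
        batch = max(1000, int(need * 1.6))
        c1 = rng.choice(len(chroms), size=batch, p=L / L.sum())
        c2 = rng.choice(len(chroms), size=batch, p=L / L.sum())
        ok = c1 != c2
        p1 = np.floor(rng.random(batch) * L[c1]).astype(np.int64)
        p2 = np.floor(rng.random(batch) * L[c2]).astype(np.int64)
        at1, at2 = kind_of(c1, p1), kind_of(c2, p2)
        w = np.where(at1 == at2, params.same_type_affinity, 1.0)
        if cent_pos and params.centromere_boost != 1.0:
            near1 = np.zeros(batch, dtype=bool)
            near2 = np.zeros(batch, dtype=bool)
            for c in chroms:
                if c in cent_pos:
                    half = params.centromere_window // 2
                    near1 |= (c1 == chrom_index[c]) & (np.abs(p1 - cent_pos[c]) <= half)
                    near2 |= (c2 == chrom_index[c]) & (np.abs(p2 - cent_pos[c]) <= half)
            w = w * np.where(near1 & near2, params.centromere_boost, 1.0)
        ok &= rng.random(batch) < (w / wc_max)
        sel = np.flatnonzero(ok)[: min(need, int(ok.sum()))]
        out_c1.append(c1[sel])
        out_p1.append(p1[sel])
        out_c2.append(c2[sel])
        out_p2.append(p2[sel])
        need -= len(sel)

    name = np.array(chroms, dtype=object)
    if out_c1:
        df = pd.DataFrame(
            {
                "chrom1": name[np.concatenate(out_c1)],
                "pos1": np.concatenate(out_p1),
                "chrom2": name[np.concatenate(out_c2)],
                "pos2": np.concatenate(out_p2),
            }
        )
    else:
        df = pd.DataFrame(columns=["chrom1", "pos1", "chrom2", "pos2"])
    df["mapq1"] = 60
    df["mapq2"] = 60
    if params.contaminant_fraction > 0 and len(df):
        bad = rng.random(len(df)) < params.contaminant_fraction
        df.loc[bad, ["mapq1", "mapq2"]] = 0
    return df[PAIR_COLUMNS]


# ---------------------------------------------------------------------------
# expression simulation
# ---------------------------------------------------------------------------

class ExpressionResult(NamedTuple):
    table: pd.DataFrame
    tad_effects: pd.Series  # planted per-TAD shared effect
    de_genes: pd.Index  # gene_ids given the planted boost


def simulate_expression(
    genes: pd.DataFrame,
    tads: pd.DataFrame | None,
    mites: pd.DataFrame | None,
    params: ExpressionSimParams,
) -> ExpressionResult:
    """Log2 fold-changes: shared per-TAD effect + iid residual (+ planted DE).

    When ``mite_fold > 1`` the planted DE set is drawn so that the rate of
    MITE-within-window genes among DE genes is ``mite_fold`` times the rate
    among the rest (exact-count construction), emulating regulatory repeats
    enriched near up-regulated genes.
    """
    rng = substream(params.seed, "expression")
    tab = genes[["gene_id", "chrom", "start", "end", "strand"]].copy()
    mid = (tab["start"] + tab["end"]) // 2
    tad_id = np.full(len(tab), "", dtype=object)
    if tads is not None and len(tads):
        for _, t in tads.iterrows():
            m = (tab["chrom"] == t["chrom"]) & (mid >= t["start"]) & (mid < t["end"])
            tad_id[m.to_numpy()] = t["tad_id"]
    tab["tad_id"] = tad_id
    unique_tads = [t for t in pd.unique(tad_id) if t]
    effects = pd.Series(
        rng.normal(0.0, params.tad_effect_sd, size=len(unique_tads)), index=unique_tads
    )
    lfc = rng.normal(0.0, params.residual_sd, size=len(tab))
    for t, e in effects.items():
        lfc[tad_id == t] += e

    de_idx = np.array([], dtype=int)
    if params.n_de_fraction > 0 and len(tab):
        n_de = max(1, int(round(params.n_de_fraction * len(tab))))
        near = np.zeros(len(tab), dtype=bool)
        if mites is not None and len(mites):
            for c in tab["chrom"].unique():
                gm = tab["chrom"] == c
                msub = mites[mites["chrom"] == c]
                if not len(msub):
                    continue
                gs = tab.loc[gm, "start"].to_numpy() - params.mite_window
                ge = tab.loc[gm, "end"].to_numpy() + params.mite_window
                ms, me = msub["start"].to_numpy(), msub["end"].to_numpy()
                hit = np.array(
                    [bool(((me > s) & (ms < e)).any()) for s, e in zip(gs, ge)]
                )
                near[np.flatnonzero(gm.to_numpy())] = hit
        if params.mite_fold > 1.0 and near.any():
            # exact-count construction of the target rate ratio
            N, q, m = len(tab), n_de / len(tab), near.mean()
            x = params.mite_fold * q * m * N / (1 - q + params.mite_fold * q)
            x = int(round(min(x, near.sum(), n_de)))
            near_ids = np.flatnonzero(near)
            far_ids = np.flatnonzero(~near)
            pick = np.concatenate(
                [
                    rng.choice(near_ids, size=x, replace=False),
                    rng.choice(far_ids, size=n_de - x, replace=False),
                ]
            )
        else:
            pick = rng.choice(len(tab), size=n_de, replace=False)
        de_idx = np.sort(pick)
        lfc[de_idx] += params.de_boost

    tab["lfc"] = lfc
    tab["mean_expr"] = np.round(rng.lognormal(3.0, 1.0, size=len(tab)), 3)
    tab["class_labels"] = ""
    order = [
        "gene_id", "chrom", "start", "end", "strand", "lfc", "mean_expr",
        "class_labels", "tad_id",
    ]
    return ExpressionResult(tab[order], effects, tab["gene_id"].iloc[de_idx].reset_index(drop=True) if len(de_idx) else pd.Index([], dtype=object))


def plant_proximity_class(
    genes: pd.DataFrame,
    blocks: pd.DataFrame,
    odds_ratio: float,
    base_rate: float = 0.05,
    max_dist: int = 5_000,
    label: str = "specific",
    seed: int = 0,
) -> pd.Series:
    """Binary gene-class labels with a planted proximity odds ratio.

    Genes within ``max_dist`` of an AT-rich block get the class label with
    odds ``odds_ratio`` times the baseline odds, so the class is planted at
    a known association strength with AT-block proximity.
    """
    from .utils import interval_distance

    rng = substream(seed, "class-plant")
    near = np.zeros(len(genes), dtype=bool)
    at = blocks[blocks["kind"] == "AT"]
    for c in genes["chrom"].unique():
        gm = (genes["chrom"] == c).to_numpy()
        sub = at[at["chrom"] == c]
        d = interval_distance(
            genes.loc[gm, "start"].to_numpy(),
            genes.loc[gm, "end"].to_numpy(),
            sub["start"].to_numpy(),
            sub["end"].to_numpy(),
        )
        near[gm] = d <= max_dist
    base_odds = base_rate / (1 - base_rate)
    p_near = base_odds * odds_ratio / (1 + base_odds * odds_ratio)
    p = np.where(near, p_near, base_rate)
    return pd.Series(np.where(rng.random(len(genes)) < p, label, ""), index=genes.index)


# ---------------------------------------------------------------------------
# 6mA call simulation
# ---------------------------------------------------------------------------

def simulate_mod_calls(
    genome: GenomeSequence,
    blocks: pd.DataFrame,
    rate_at: float = 4.2e-4,
    rate_gc: float = 3.8e-4,
    qv_fail_fraction: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """6mA calls over adenines (both strands) at per-compartment rates.

    ``rate_at``/``rate_gc`` are the rates of *confident* calls (the
    fractions the downstream summary recovers after its mQV filter; defaults
    0.042% / 0.038%). On top of those, spurious calls amounting to
    ``qv_fail_fraction`` of the confident rate are emitted below the mQV 20
    threshold to exercise the filter.
    """
    rng = substream(seed, "mod-calls")
    rows = []
    for chrom, seq in genome.records.items():
        arr = seq_to_array(seq)
        sub = blocks[blocks["chrom"] == chrom].sort_values("start")
        starts = sub["start"].to_numpy()
        is_at = (sub["kind"] == "AT").to_numpy()
        for strand, base in (("+", b"A"), ("-", b"T")):
            pos = np.flatnonzero(arr == base)
            idx = np.searchsorted(starts, pos, side="right") - 1
            at_here = is_at[np.clip(idx, 0, len(is_at) - 1)]
            rate = np.where(at_here, rate_at, rate_gc)
            u = rng.random(len(pos))
            for p in pos[u < rate]:
                rows.append(
                    {"chrom": chrom, "pos": int(p), "strand": strand,
                     "modqv": round(float(rng.uniform(21, 60)), 1)}
                )
            lo, hi = rate, rate * (1 + qv_fail_fraction)
            for p in pos[(u >= lo) & (u < hi)]:
                rows.append(
                    {"chrom": chrom, "pos": int(p), "strand": strand,
                     "modqv": round(float(rng.uniform(5, 19.5)), 1)}
                )
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "modqv"])
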