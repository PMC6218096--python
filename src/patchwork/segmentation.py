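"""AT-rich / GC-rich genome segmentation from windowed GC content.

A two-component Gaussian mixture is fitted to the window GC distribution
(the bimodal signature of RIP-eroded fungal genomes), windows are
classified at equal posterior, same-class runs are merged and short runs
absorbed into their flanks. Composition summaries mirror the standard
per-component table: peak GC, mean block length, totals, repeat/exon
megabases and (double-counted boundary) gene counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io_formats import GenomeSequence
from .utils import covered_length_within, overlap_length, seq_to_array


@dataclass
class GcTrack:
    """Windowed GC content per chromosome (last window may be short)."""

    windows: pd.DataFrame  # chrom, start, end, gc, n_fraction
    window_size: int


@dataclass
class SegmentationResult:
    blocks: pd.DataFrame  # chrom, start, end, kind
    peak_at: float
    peak_gc: float
    unimodal: bool = False


def gc_track(genome: GenomeSequence, window_size: int = 1_000) -> GcTrack:
    """GC fraction (over unambiguous bases) per tiling window.

    Windows with more than half N have ``n_fraction > 0.5`` and are treated
    as uninformative by the segmenter.
    """
    if window_size < 100:
        raise ValueError("window_size must be >= 100")
    rows = []
    for chrom, seq in genome.records.items():
        arr = seq_to_array(seq)
        n = len(arr)
        for start in range(0, n, window_size):
            end = min(start + window_size, n)
            w = arr[start:end]
            gc = int(np.count_nonzero((w == b"G") | (w == b"C")))
            at = int(np.count_nonzero((w == b"A") | (w == b"T")))
            n_count = len(w) - gc - at
            rows.append(
                {
                    "chrom": chrom,
                    "start": start,
                    "end": end,
                    "gc": gc / (gc + at) if gc + at else np.nan,
                    "n_fraction": n_count / len(w),
                }
            )
    return GcTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "gc", "n_fraction"]), window_size)


def _absorb_short_runs(kinds: np.ndarray, lengths: np.ndarray, min_len: int) -> np.ndarray:
    """Flip runs shorter than min_len into their flanking class.

    Runs are processed shortest-first so that lowering ``min_len`` can only
    preserve or increase the number of surviving intervals.
    """
    kinds = kinds.copy()
    while True:
        # current runs
        runs = []
        i = 0
        while i < len(kinds):
            j = i
            while j < len(kinds) and kinds[j] == kinds[i]:
                j += 1
            runs.append((i, j, int(lengths[i:j].sum())))
            i = j
        short = [r for r in runs if r[2] < min_len]
        if not short or len(runs) == 1:
            return kinds
        i0, j0, _ = min(short, key=lambda r: r[2])
        kinds[i0:j0] = ~kinds[i0]
        # merging happens implicitly on the next pass


def segment_at_rich(
    track: GcTrack,
    min_block_len: int = 2_000,
    min_separation: float = 0.08,
    random_state: int = 0,
) -> SegmentationResult:
    """Classify windows into AT-rich vs GC-rich blocks via a 2-Gaussian EM fit.

    If the two fitted means are closer than ``min_separation`` the GC
    distribution is treated as unimodal: the whole genome is labelled GC and
    the result flagged.
    """
    win = track.windows.copy()
    if not len(win):
        raise ValueError("empty GC track")
    # impute windows dominated by N with their chromosome's mean GC
    for chrom in win["chrom"].unique():
        m = win["chrom"] == chrom
        bad = m & ((win["n_fraction"] > 0.5) | win["gc"].isna())
        good_mean = win.loc[m & ~bad, "gc"].mean()
        win.loc[bad, "gc"] = good_mean if np.isfinite(good_mean) else 0.5
    x = win["gc"].to_numpy().reshape(-1, 1)
    gm = GaussianMixture(n_components=2, random_state=random_state, n_init=3)
    gm.fit(x)
    means = gm.means_.ravel()
    lo, hi = int(np.argmin(means)), int(np.argmax(means))
    if abs(means[hi] - means[lo]) < min_separation:
        blocks = (
            win.groupby("chrom", sort=False)
            .agg(start=("start", "min"), end=("end", "max"))
            .reset_index()
        )
        blocks["kind"] = "GC"
        return SegmentationResult(
            blocks[["chrom", "start", "end", "kind"]],
            peak_at=float(means[lo]),
            peak_gc=float(means[hi]),
            unimodal=True,
        )
    post = gm.predict_proba(x)
    is_at_win = post[:, lo] > 0.5
    rows = []
    for chrom in win["chrom"].unique():
        m = (win["chrom"] == chrom).to_numpy()
        kinds = is_at_win[m]
        sub = win.loc[m]
        lengths = (sub["end"] - sub["start"]).to_numpy()
        kinds = _absorb_short_runs(kinds, lengths, min_block_len)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        i = 0
        while i < len(kinds):
            j = i
            while j < len(kinds) and kinds[j] == kinds[i]:
                j += 1
            rows.append(
                {
                    "chrom": chrom,
                    "start": int(starts[i]),
                    "end": int(ends[j - 1]),
                    "kind": "AT" if kinds[i] else "GC",
                }
            )
            i = j
    return SegmentationResult(
        pd.DataFrame(rows), peak_at=float(means[lo]), peak_gc=float(means[hi])
    )


def composition_summary(
    blocks: pd.DataFrame,
    repeats: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    exons: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-kind composition: peak/mean GC proxy, lengths, totals, content.

    Repeat Mb counts block bases covered by at least one repeat; exon Mb is
    the analogue for exons (gene bodies stand in when no exon table is
    given). A gene overlapping both an AT and a GC block is counted in both
    kinds, so block-spanning genes are deliberately double counted.
    """
    chrom_ends = blocks.groupby("chrom")["end"].max()
    for df, label in ((repeats, "repeat"), (genes, "gene"), (exons, "exon")):
        if df is None or not len(df):
            continue
        ends = df["chrom"].map(chrom_ends)
        bad = ends.isna() | (df["end"] > ends) | (df["start"] < 0)
        if bad.any():
            r = df.loc[bad.idxmax()]
            name = r.get("gene_id", r.get("copy_id", "?"))
            raise ValueError(f"{label} annotation {name} lies off the end of {r['chrom']}")
    if exons is None:
        exons = genes
    rows = []
    for kind in ("AT", "GC"):
        sub = blocks[blocks["kind"] == kind]
        lengths = (sub["end"] - sub["start"]).to_numpy()
        rep_bases = 0
        exon_bases = 0
        gene_ids: set = set()
        for _, b in sub.iterrows():
            if repeats is not None and len(repeats):
                rsub = repeats[repeats["chrom"] == b["chrom"]]
                rep_bases += covered_length_within(
                    b["start"], b["end"], rsub["start"].to_numpy(), rsub["end"].to_numpy()
                )
            if exons is not None and len(exons):
                esub = exons[exons["chrom"] == b["chrom"]]
                exon_bases += covered_length_within(
                    b["start"], b["end"], esub["start"].to_numpy(), esub["end"].to_numpy()
                )
            if genes is not None and len(genes):
                gsub = genes[genes["chrom"] == b["chrom"]]
                ov = overlap_length(
                    b["start"], b["end"], gsub["start"].to_numpy(), gsub["end"].to_numpy()
                )
                gene_ids.update(gsub.loc[ov > 0, "gene_id"])
        rows.append(
            {
                "kind": kind,
                "n_blocks": len(sub),
                "mean_length_kb": lengths.mean() / 1e3 if len(sub) else np.nan,
                "sd_length_kb": lengths.std(ddof=1) / 1e3 if len(sub) > 1 else np.nan,
                "total_mb": lengths.sum() / 1e6,
                "repeat_mb": rep_bases / 1e6,
                "exon_mb": exon_bases / 1e6,
                "genes": len(gene_ids),
            }
        )
    return pd.DataFrame(rows)
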