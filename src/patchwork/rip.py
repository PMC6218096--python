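"""RIP quantification, alignment masking, invasion dating and repeat nesting.

The RIP (repeat-induced point mutation) index is the Margolin dinucleotide
ratio (CpA+TpG)/(ApC+GpT): RIP mutates C->T preferentially at CpA (TpG on
the complement), so affected sequences are depleted in the numerator
dinucleotides. Values below ~0.9 indicate RIP-affected sequence; the ratio
construction makes the index robust to overall AT content.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GenomeSequence
from .utils import overlap_length, seq_to_array


@dataclass
class RipRecord:
    target_id: str
    n_ca: int
    n_tg: int
    n_ac: int
    n_gt: int

    @property
    def defined(self) -> bool:
        return (self.n_ac + self.n_gt) > 0

    @property
    def index(self) -> float:
        if not self.defined:
            return float("nan")
        return (self.n_ca + self.n_tg) / (self.n_ac + self.n_gt)


def _dinucleotide_counts(seq: str) -> tuple[int, int, int, int]:
    """Overlapping (step 1) CA/TG/AC/GT counts; dinucleotides with N excluded."""
    arr = seq_to_array(seq.upper())
    if len(arr) < 2:
        return 0, 0, 0, 0
    a, b = arr[:-1], arr[1:]
    return (
        int(np.count_nonzero((a == b"C") & (b == b"A"))),
        int(np.count_nonzero((a == b"T") & (b == b"G"))),
        int(np.count_nonzero((a == b"A") & (b == b"C"))),
        int(np.count_nonzero((a == b"G") & (b == b"T"))),
    )


def rip_index(sequence: str, target_id: str = "") -> RipRecord:
    """Margolin RIP index of one sequence; undefined when ApC+GpT is zero."""
    return RipRecord(target_id, *_dinucleotide_counts(sequence))


def rip_profile(
    repeats: pd.DataFrame,
    genome: GenomeSequence,
    blocks: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-copy (and optionally per-block) RIP index table.

    Fragments of an interrupted copy are counted separately and their
    dinucleotide counts summed, which concatenates the copy in genomic order
    while excluding junction-spanning dinucleotides (those never existed as
    contiguous sequence).
    """
    rows = []
    if len(repeats):
        for (copy_id,), grp in repeats.groupby(["copy_id"], sort=False):
            grp = grp.sort_values("start")
            counts = np.zeros(4, dtype=int)
            for _, f in grp.iterrows():
                counts += np.array(
                    _dinucleotide_counts(genome[f["chrom"]][f["start"] : f["end"]])
                )
            rec = RipRecord(copy_id, *counts.tolist())
            rows.append(
                {
                    "target_id": copy_id,
                    "target_type": "copy",
                    "family": grp["family"].iloc[0],
                    "repeat_class": grp["repeat_class"].iloc[0] if "repeat_class" in grp else "unknown",
                    "rip_index": rec.index,
                    "defined": rec.defined,
                }
            )
    if blocks is not None:
        for _, b in blocks.iterrows():
            rec = rip_index(genome[b["chrom"]][b["start"] : b["end"]])
            rows.append(
                {
                    "target_id": f"{b['chrom']}:{b['start']}-{b['end']}",
                    "target_type": f"block_{b['kind']}" if "kind" in b else "block",
                    "family": "",
                    "repeat_class": "",
                    "rip_index": rec.index,
                    "defined": rec.defined,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["target_id", "target_type", "family", "repeat_class", "rip_index", "defined"],
    )
    return out


def family_medians(profile: pd.DataFrame) -> pd.Series:
    copies = profile[profile["target_type"] == "copy"]
    return copies.groupby("family")["rip_index"].median()


# ---------------------------------------------------------------------------
# alignment masking
# ---------------------------------------------------------------------------

def mask_tpa(alignment: dict[str, str]) -> dict[str, str]:
    """Replace every TpA dinucleotide with NN, per aligned sequence.

    TpA can be produced by RIP (CpA -> TpA), so masking removes the sites
    where RIP would otherwise inflate phylogenetic branch lengths. The scan
    runs over each gap-stripped sequence and maps hits back to alignment
    columns; targets are located on the original characters so overlapping
    masking cannot cascade. Alignment length is preserved.
    """
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise ValueError("ragged alignment: sequences differ in length")
    out = {}
    for name, seq in alignment.items():
        chars = list(seq)
        idx = [i for i, c in enumerate(chars) if c not in "-."]
        orig = [chars[i].upper() for i in idx]
        for k in range(len(idx) - 1):
            if orig[k] == "T" and orig[k + 1] == "A":
                chars[idx[k]] = "N"
                chars[idx[k + 1]] = "N"
        out[name] = "".join(chars)
    return out


# ---------------------------------------------------------------------------
# family filtering and dating
# ---------------------------------------------------------------------------

def near_full_length_filter(
    copies: pd.DataFrame,
    ref_len: int,
    min_frac: float = 0.85,
    min_copies: int = 10,
) -> pd.DataFrame:
    """Copies whose summed fragment length exceeds ``min_frac`` of reference.

    Returns an empty frame (family skipped) when fewer than ``min_copies``
    copies survive — families with too few near-full-length copies cannot
    support a within-family phylogeny.
    """
    if ref_len <= 0:
        raise ValueError("ref_len must be positive")
    if not len(copies):
        return copies.iloc[0:0]
    lens = (copies["end"] - copies["start"]).groupby(copies["copy_id"]).sum()
    keep = lens[lens / ref_len > min_frac].index
    if len(keep) < min_copies:
        return copies.iloc[0:0]
    return copies[copies["copy_id"].isin(keep)]


def terminal_fork_lengths(
    tree: dendropy.Tree, fork_mode: str = "cherry"
) -> np.ndarray:
    """Terminal branch lengths that date a family's last integrations.

    ``cherry`` mode (default) keeps only tips whose sibling is also a tip —
    branches from a single node that each lead directly to a tip — with both
    tips contributing. ``all-tips`` keeps every terminal branch.
    """
    leaves = tree.leaf_nodes()
    if len(leaves) < 3:
        return np.array([])
    lengths = []
    if fork_mode == "all-tips":
        for leaf in leaves:
            if leaf.edge.length is None:
                raise ValueError("tree has tips without branch lengths")
            lengths.append(leaf.edge.length)
    elif fork_mode == "cherry":
        for node in tree.preorder_internal_node_iter():
            children = node.child_nodes()
            if len(children) == 2 and all(c.is_leaf() for c in children):
                for c in children:
                    if c.edge.length is None:
                        raise ValueError("tree has tips without branch lengths")
                    lengths.append(c.edge.length)
    else:
        raise ValueError("fork_mode must be 'cherry' or 'all-tips'")
    return np.asarray(lengths, dtype=float)


# ---------------------------------------------------------------------------
# nesting
# ---------------------------------------------------------------------------

def nesting_interruptions(repeats: pd.DataFrame) -> pd.DataFrame:
    """Interruption edges: interrupted family -> interrupting family.

    For every copy split into fragments, each *maximal* copy lying strictly
    between two consecutive fragments (its extent not contained in another
    interloper's extent) is recorded as one interruption of the split copy.
    """
    cols = ["interrupted_family", "interrupted_copy", "interrupting_family", "interrupting_copy"]
    if not len(repeats):
        return pd.DataFrame(columns=cols)
    extents = repeats.groupby("copy_id").agg(
        chrom=("chrom", "first"),
        ext_start=("start", "min"),
        ext_end=("end", "max"),
        family=("family", "first"),
        n_frag=("start", "size"),
        n_chrom=("chrom", "nunique"),
    )
    multi = extents[extents["n_chrom"] > 1]
    if len(multi):
        raise ValueError(
            f"fragments of copy {multi.index[0]} lie on different chromosomes"
        )
    rows = []
    for copy_id, grp in repeats.groupby("copy_id"):
        if len(grp) < 2:
            continue
        grp = grp.sort_values("start")
        chrom = grp["chrom"].iloc[0]
        fam = grp["family"].iloc[0]
        for (_, f1), (_, f2) in zip(grp.iloc[:-1].iterrows(), grp.iloc[1:].iterrows()):
            gap_start, gap_end = f1["end"], f2["start"]
            cand = extents[
                (extents["chrom"] == chrom)
                & (extents.index != copy_id)
                & (extents["ext_start"] >= gap_start)
                & (extents["ext_end"] <= gap_end)
            ]
            for cid, c in cand.iterrows():
                others = cand[(cand.index != cid)]
                contained = (
                    (others["ext_start"] <= c["ext_start"])
                    & (others["ext_end"] >= c["ext_end"])
                    & (
                        (others["ext_start"] < c["ext_start"])
                        | (others["ext_end"] > c["ext_end"])
                    )
                ).any()
                if not contained:
                    rows.append(
                        {
                            "interrupted_family": fam,
                            "interrupted_copy": copy_id,
                            "interrupting_family": c["family"],
                            "interrupting_copy": cid,
                        }
                    )
    return pd.DataFrame(rows, columns=cols)


def interruption_graph(edges: pd.DataFrame) -> nx.MultiDiGraph:
    """Directed multigraph over families; one edge per interruption event."""
    g = nx.MultiDiGraph()
    for _, e in edges.iterrows():
        g.add_edge(
            e["interrupted_family"],
            e["interrupting_family"],
            interrupted_copy=e["interrupted_copy"],
            interrupting_copy=e["interrupting_copy"],
        )
    return g


# ---------------------------------------------------------------------------
# family statistics
# ---------------------------------------------------------------------------

def repeat_family_stats(
    repeats: pd.DataFrame,
    blocks: pd.DataFrame,
    family_refs: pd.DataFrame,
) -> pd.DataFrame:
    """Per-family totals, effective copy number and AT-block share.

    ``family_refs`` needs columns family, repeat_class, ref_len. Effective
    copy number is total annotated length / reference length; ``prop_AT`` is
    the fraction of annotated bases falling inside AT-rich blocks.
    """
    refs = family_refs.set_index("family")
    missing = set(repeats["family"].unique()) - set(refs.index)
    if missing:
        raise ValueError(f"annotated families missing from references: {sorted(missing)}")
    at_blocks = blocks[blocks["kind"] == "AT"]
    rows = []
    for fam, grp in repeats.groupby("family"):
        total = int((grp["end"] - grp["start"]).sum())
        at_bases = 0
        for _, f in grp.iterrows():
            sub = at_blocks[at_blocks["chrom"] == f["chrom"]]
            at_bases += int(
                overlap_length(
                    f["start"], f["end"], sub["start"].to_numpy(), sub["end"].to_numpy()
                ).sum()
            )
        ref_len = int(refs.loc[fam, "ref_len"])
        rows.append(
            {
                "family": fam,
                "repeat_class": refs.loc[fam, "repeat_class"],
                "total_kbp": total / 1e3,
                "effective_copy_number": total / ref_len,
                "n_hits": len(grp),
                "mean_hit_length": (grp["end"] - grp["start"]).mean(),
                "prop_AT": at_bases / total if total else np.nan,
                "ref_len": ref_len,
            }
        )
    return pd.DataFrame(rows).sort_values("family").reset_index(drop=True)
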