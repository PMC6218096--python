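"""Readers and writers for every on-disk format the pipeline touches.

Coordinate conventions are strict and declared, never sniffed: BED is
0-based half-open, GFF3 is 1-based closed; everything is converted to
0-based half-open at the boundary and converted back exactly on write.
All readers are gzip-transparent (``.gz`` paths).
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from typing import Iterable

import dendropy
import pandas as pd
from Bio import SeqIO

_VALID_BASES = set("ACGTN")


@dataclass
class GenomeSequence:
    """Ordered named chromosome sequences over {A,C,G,T,N}."""

    records: dict[str, str]

    def __post_init__(self):
        for name, seq in self.records.items():
            bad = set(seq) - _VALID_BASES
            if bad:
                pos = next(i for i, c in enumerate(seq) if c in bad)
                raise ValueError(
                    f"non-IUPAC character {seq[pos]!r} in record {name!r} at position {pos}"
                )

    @property
    def names(self) -> list[str]:
        return list(self.records)

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self.records.items()}

    def __getitem__(self, name: str) -> str:
        return self.records[name]

    def __len__(self) -> int:
        return len(self.records)

    def total_length(self) -> int:
        return sum(len(s) for s in self.records.values())


def _open_text(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    """Read a FASTA file; sequences are uppercased, duplicate names rejected."""
    records: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA record name {rec.id!r}")
            records[rec.id] = str(rec.seq).upper()
    return GenomeSequence(records)


def write_fasta(genome: GenomeSequence, path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Intervals: BED6 (0-based half-open) and GFF3 (1-based closed)
# ---------------------------------------------------------------------------

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_intervals(path, dialect: str) -> pd.DataFrame:
    """Parse intervals into a 0-based half-open DataFrame.

    ``dialect`` must be ``"BED"`` or ``"GFF3"``; it is never guessed from the
    file. GFF3 attribute key=value pairs become extra columns.
    """
    if dialect == "BED":
        return _read_bed(path)
    if dialect == "GFF3":
        return _read_gff3(path)
    raise ValueError(f"unknown dialect {dialect!r}; use 'BED' or 'GFF3'")


def _read_bed(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if " " in line.split("\t")[0] or ("\t" not in line and " " in line):
                raise ValueError(f"line {lineno}: BED fields must be tab-separated")
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"line {lineno}: BED needs >=3 columns")
            start, end = int(fields[1]), int(fields[2])
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start")
            row = {"chrom": fields[0], "start": start, "end": end}
            for col, val in zip(BED_COLUMNS[3:], fields[3:]):
                row[col] = val
            rows.append(row)
    df = pd.DataFrame(rows, columns=[c for c in BED_COLUMNS if rows and c in rows[0]] or BED_COLUMNS[:3])
    if "score" in df.columns:
        df["score"] = pd.to_numeric(df["score"], errors="coerce")
    return df


def _read_gff3(path) -> pd.DataFrame:
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"line {lineno}: GFF3 needs 9 tab-separated columns")
            start1, end1 = int(fields[3]), int(fields[4])
            start, end = start1 - 1, end1  # 1-based closed -> 0-based half-open
            if end <= start:
                raise ValueError(f"line {lineno}: end <= start after conversion")
            row = {
                "chrom": fields[0],
                "source": fields[1],
                "type": fields[2],
                "start": start,
                "end": end,
                "score": fields[5],
                "strand": fields[6],
                "phase": fields[7],
            }
            for pair in fields[8].split(";"):
                if not pair:
                    continue
                key, _, val = pair.partition("=")
                row[key.strip()] = val
            rows.append(row)
    return pd.DataFrame(rows)


def write_intervals(df: pd.DataFrame, path, dialect: str, attribute_cols: Iterable[str] = ()) -> None:
    if dialect == "BED":
        cols = [c for c in BED_COLUMNS if c in df.columns]
        out = df[cols].copy()
        with _open_text(path, "wt") as fh:
            for _, r in out.iterrows():
                fh.write("\t".join(str(r[c]) for c in cols) + "\n")
    elif dialect == "GFF3":
        with _open_text(path, "wt") as fh:
            fh.write("##gff-version 3\n")
            for _, r in df.iterrows():
                attrs = ";".join(f"{c}={r[c]}" for c in attribute_cols if pd.notna(r.get(c)))
                fh.write(
                    "\t".join(
                        [
                            str(r["chrom"]),
                            str(r.get("source", "patchwork")),
                            str(r.get("type", "region")),
                            str(int(r["start"]) + 1),  # back to 1-based closed
                            str(int(r["end"])),
                            str(r.get("score", ".")),
                            str(r.get("strand", ".")),
                            str(r.get("phase", ".")),
                            attrs or ".",
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Contact pairs, expression tables, generic typed tables
# ---------------------------------------------------------------------------

PAIR_COLUMNS = ["chrom1", "pos1", "chrom2", "pos2", "mapq1", "mapq2"]


def read_pairs(path) -> pd.DataFrame:
    """Read positional Hi-C pairs.

    Accepts either the 6-column form (mapq per end) or the 5-column form with
    a single ``mapq`` applied to both ends.
    """
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:4]) != PAIR_COLUMNS[:4]:
        raise ValueError(f"pairs file must start with columns {PAIR_COLUMNS[:4]}")
    if "mapq" in df.columns:
        df["mapq1"] = df["mapq"]
        df["mapq2"] = df["mapq"]
        df = df.drop(columns=["mapq"])
    if "mapq1" not in df.columns or "mapq2" not in df.columns:
        raise ValueError("pairs file missing mapq column(s)")
    if df[["pos1", "pos2", "mapq1", "mapq2"]].isna().any().any():
        bad = int(df[["pos1", "pos2", "mapq1", "mapq2"]].isna().any(axis=1).idxmax())
        raise ValueError(f"missing numeric value in pairs row {bad}")
    return df[PAIR_COLUMNS]


def write_pairs(df: pd.DataFrame, path) -> None:
    df[PAIR_COLUMNS].to_csv(path, sep="\t", index=False)


EXPRESSION_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "lfc", "mean_expr", "class_labels"]


def read_expression(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"class_labels": str})
    missing = [c for c in EXPRESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"expression table missing columns {missing}")
    df["class_labels"] = df["class_labels"].fillna("")
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df[EXPRESSION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_table(path, schema: dict[str, type]) -> pd.DataFrame:
    """Read a TSV with a declared column->dtype schema; violations name the column."""
    df = pd.read_csv(path, sep="\t")
    for col, typ in schema.items():
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"column {col!r} does not parse as {typ}: {exc}") from exc
    return df


def read_mod_calls(path) -> pd.DataFrame:
    return read_table(path, {"chrom": str, "pos": int, "strand": str, "modqv": float})


def write_mod_calls(df: pd.DataFrame, path) -> None:
    df[["chrom", "pos", "strand", "modqv"]].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def tree_from_string(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# Contact matrix as COO text triplets + bin table
# ---------------------------------------------------------------------------

def write_contact_matrix(matrix, prefix) -> None:
    """Persist as ``<prefix>.bins.tsv`` and ``<prefix>.coo.tsv`` (upper triangle)."""
    from scipy import sparse

    prefix = str(prefix)
    matrix.bins.to_csv(prefix + ".bins.tsv", sep="\t", index=False)
    coo = sparse.triu(matrix.counts).tocoo()
    pd.DataFrame({"bin_i": coo.row, "bin_j": coo.col, "count": coo.data}).to_csv(
        prefix + ".coo.tsv", sep="\t", index=False
    )


def read_contact_matrix(prefix):
    from scipy import sparse

    from .hic import ContactMatrix

    prefix = str(prefix)
    bins = pd.read_csv(prefix + ".bins.tsv", sep="\t")
    coo = pd.read_csv(prefix + ".coo.tsv", sep="\t")
    n = len(bins)
    upper = sparse.coo_matrix(
        (coo["count"], (coo["bin_i"], coo["bin_j"])), shape=(n, n)
    ).tocsr()
    diag = sparse.diags(upper.diagonal())
    counts = upper + upper.T - diag
    bin_size = int((bins["end"] - bins["start"]).max())
    return ContactMatrix(bins=bins, counts=counts.tocsr(), bin_size=bin_size)
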