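"""Shared helpers: seeded substreams, sequence codecs, interval arithmetic.

All genomic intervals are 0-based half-open in memory; conversions to and
from 1-based closed (GFF3) happen only in :mod:`patchwork.io_formats`.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def substream(seed: int, *labels) -> np.random.Generator:
    """Derive an independent, reproducible RNG from a global seed and labels.

    Stage names (and optional integer indices) select a named substream so
    each pipeline stage is independently reproducible from one integer seed.
    """
    entropy = [seed] + [
        lab if isinstance(lab, int) else int.from_bytes(str(lab).encode(), "little") % (2**32)
        for lab in labels
    ]
    return np.random.default_rng(np.random.SeedSequence(entropy))


def seq_to_array(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype="S1")


def array_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """GC over unambiguous bases; NaN if no A/C/G/T present."""
    arr = seq_to_array(seq.upper())
    gc = int(np.count_nonzero((arr == b"G") | (arr == b"C")))
    at = int(np.count_nonzero((arr == b"A") | (arr == b"T")))
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def random_sequence(rng: np.random.Generator, length: int, gc: float) -> str:
    """Random sequence with *exact* base counts matching the GC target.

    Composing from exact counts (rather than iid draws) pins the realized GC
    of every block to the target up to 1-base rounding.
    """
    n_gc = int(round(gc * length))
    n_at = length - n_gc
    bases = np.empty(length, dtype="S1")
    bases[: n_gc // 2] = b"G"
    bases[n_gc // 2 : n_gc] = b"C"
    bases[n_gc : n_gc + n_at // 2] = b"A"
    bases[n_gc + n_at // 2 :] = b"T"
    rng.shuffle(bases)
    return array_to_seq(bases)


# ---------------------------------------------------------------------------
# interval arithmetic on (start, end) ndarray pairs, half-open
# ---------------------------------------------------------------------------

def merge_intervals(starts: np.ndarray, ends: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of possibly-overlapping intervals, returned sorted and disjoint."""
    if len(starts) == 0:
        return np.array([], dtype=int), np.array([], dtype=int)
    order = np.argsort(starts, kind="stable")
    s, e = np.asarray(starts)[order], np.asarray(ends)[order]
    out_s, out_e = [int(s[0])], [int(e[0])]
    for a, b in zip(s[1:], e[1:]):
        if a <= out_e[-1]:
            out_e[-1] = max(out_e[-1], int(b))
        else:
            out_s.append(int(a))
            out_e.append(int(b))
    return np.array(out_s), np.array(out_e)


def overlap_length(a_start, a_end, b_starts, b_ends) -> np.ndarray:
    """Overlap of one interval against arrays of intervals."""
    return np.maximum(
        0, np.minimum(a_end, np.asarray(b_ends)) - np.maximum(a_start, np.asarray(b_starts))
    )


def covered_length_within(
    span_start: int, span_end: int, starts: np.ndarray, ends: np.ndarray
) -> int:
    """Bases of [span_start, span_end) covered by the union of intervals."""
    ms, me = merge_intervals(np.asarray(starts), np.asarray(ends))
    return int(overlap_length(span_start, span_end, ms, me).sum())


def interval_distance(
    q_starts: np.ndarray, q_ends: np.ndarray, t_starts: np.ndarray, t_ends: np.ndarray
) -> np.ndarray:
    """Gap between each query interval and its nearest target (0 if touching/overlapping)."""
    q_starts = np.asarray(q_starts)
    q_ends = np.asarray(q_ends)
    out = np.full(len(q_starts), np.inf)
    if len(t_starts) == 0:
        return out
    ts, te = np.asarray(t_starts), np.asarray(t_ends)
    for i, (qs, qe) in enumerate(zip(q_starts, q_ends)):
        gap = np.maximum(ts - qe, qs - te)
        out[i] = max(0, int(gap.min())) if len(gap) else np.inf
        if (gap <= 0).any():
            out[i] = 0
    return out
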