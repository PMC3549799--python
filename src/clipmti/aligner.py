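"""Self-contained ungapped alignment of short reads to 3'UTR references.

Reads from Argonaute CLIP libraries are sense-strand fragments of mature
transcripts, so mapping is restricted to the forward strand of 3'UTR
sequences and allows only substitutions (at most ``max_mismatch``, default
1).  The index is an exhaustive k-mer table; queries use the pigeonhole
principle: a read split into ``max_mismatch + 1`` parts must match one part
exactly, so seeding each part's leading k-mer and verifying the full read by
Hamming comparison is complete.  Reads too short for that split fall back to
an exhaustive scan of every offset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional

from .io_formats import UtrReference

__all__ = ["RawAlignment", "MappedRead", "UtrIndex", "build_index", "align"]


class RawAlignment(NamedTuple):
    """A candidate placement of a (possibly reverted) sequence on a UTR."""

    utr_id: str
    start: int  # 0-based offset on the UTR
    mismatches: tuple[int, ...]  # 0-based offsets within the placement


@dataclass(frozen=True)
class MappedRead:
    """A read placed on one UTR after variant reconciliation.

    ``mismatch_positions`` and ``conversion_positions`` are 0-based offsets
    within the mapped span; a conversion is a read C over a reference T (the
    PAR-CLIP crosslink signature) and is disjoint from the mismatch set.
    """

    read_id: str
    multiplicity: int
    utr_id: str
    start: int
    end: int
    mismatch_positions: frozenset[int] = frozenset()
    conversion_positions: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError("invalid mapped interval")
        if self.mismatch_positions & self.conversion_positions:
            raise ValueError("mismatch and conversion positions must be disjoint")


@dataclass
class UtrIndex:
    """Exhaustive forward-strand k-mer table over a UTR reference set."""

    sequences: dict[str, str]
    k: int
    table: dict[str, list[tuple[str, int]]] = field(repr=False)


def build_index(utrs: Iterable[UtrReference], k: int = 10) -> UtrIndex:
    """Index every length-k substring of every UTR.

    UTRs shorter than k cannot be indexed and are skipped with a warning.
    """
    if k < 8:
        raise ValueError("seed length k must be >= 8")
    utrs = list(utrs)
    if not utrs:
        raise ValueError("empty reference set")
    sequences: dict[str, str] = {}
    table: dict[str, list[tuple[str, int]]] = {}
    n_indexed = 0
    for utr in utrs:
        seq = utr.sequence
        if len(seq) < k:
            warnings.warn(
                f"UTR {utr.utr_id!r} shorter than seed length {k}; skipped",
                stacklevel=2,
            )
            continue
        sequences[utr.utr_id] = seq
        n_indexed += 1
        for i in range(len(seq) - k + 1):
            table.setdefault(seq[i : i + k], []).append((utr.utr_id, i))
    if n_indexed == 0:
        raise ValueError("no UTR is long enough to index")
    return UtrIndex(sequences=sequences, k=k, table=table)


def _hamming_check(seq: str, ref: str, start: int, limit: int) -> Optional[tuple[int, ...]]:
    """Mismatch offsets of seq against ref[start:start+len(seq)], or None if > limit."""
    mismatches: list[int] = []
    for i, base in enumerate(seq):
        if base != ref[start + i]:
            mismatches.append(i)
            if len(mismatches) > limit:
                return None
    return tuple(mismatches)


def align(seq: str, index: UtrIndex, max_mismatch: int = 1) -> list[RawAlignment]:
    """All forward-strand placements of ``seq`` with <= max_mismatch substitutions.

    Returns placements sorted by (utr_id, start); an empty list means
    unmapped.  No gaps are considered.
    """
    n = len(seq)
    hits: list[RawAlignment] = []
    n_parts = max_mismatch + 1
    if n < n_parts * index.k:
        # too short for the pigeonhole split: scan every offset exhaustively
        for utr_id in sorted(index.sequences):
            ref = index.sequences[utr_id]
            for start in range(len(ref) - n + 1):
                mm = _hamming_check(seq, ref, start, max_mismatch)
                if mm is not None:
                    hits.append(RawAlignment(utr_id, start, mm))
        return hits

    seen: set[tuple[str, int]] = set()
    part_bounds = [n * i // n_parts for i in range(n_parts)]
    for offset in part_bounds:
        postings = index.table.get(seq[offset : offset + index.k])
        if not postings:
            continue
        for utr_id, pos in postings:
            start = pos - offset
            if start < 0:
                continue
            ref = index.sequences[utr_id]
            if start + n > len(ref):
                continue
            key = (utr_id, start)
            if key in seen:
                continue
            seen.add(key)
            mm = _hamming_check(seq, ref, start, max_mismatch)
            if mm is not None:
                hits.append(RawAlignment(utr_id, start, mm))
    hits.sort(key=lambda h: (h.utr_id, h.start))
    return hits
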