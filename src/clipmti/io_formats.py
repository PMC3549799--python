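"""Readers and writers for the formats the pipeline touches.

Sequencing reads come in as 4-line FASTQ, references and mature miRNAs as
FASTA, and the side tables (miRNA expression, experimentally validated
miRNA-target pairs, per-UTR conservation flags) as two-column TSV.  The
pipeline's own outputs are plain TSV so they can be diffed and loaded into
pandas without ceremony.

Coordinates in reports are 1-based inclusive (the way target sites are
displayed in the miRNA field); everything internal is 0-based half-open.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._dna import normalize

__all__ = [
    "SequencedRead",
    "UtrReference",
    "MatureMirna",
    "FastqFormatError",
    "read_fastq",
    "write_fastq",
    "read_fasta",
    "load_utrs",
    "load_mirnas",
    "read_two_column_tsv",
    "load_expression",
    "load_validated",
    "load_conservation",
    "write_site_report",
]

SITE_REPORT_COLUMNS = [
    "utr_id",
    "mirna_id",
    "site_start",
    "site_end",
    "seed_match_type",
    "cluster_id",
    "read_support",
    "conversion_read_fraction",
    "validated_flag",
    "expression",
    "rank",
]


class FastqFormatError(ValueError):
    """Malformed FASTQ record; the message names the 1-based record index."""


@dataclass
class SequencedRead:
    """A sequencing read; after collapsing, ``multiplicity`` counts the
    identical originals merged into this record."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    multiplicity: int = 1

    def __post_init__(self) -> None:
        self.quals = tuple(self.quals)
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality scores"
            )
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class UtrReference:
    """A 3'UTR reference sequence (mRNA sense strand)."""

    utr_id: str
    sequence: str
    conserved: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"UTR {self.utr_id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class MatureMirna:
    """A mature miRNA, 5'->3'; stored as DNA (U -> T)."""

    mirna_id: str
    sequence: str
    expression: Optional[float] = None

    def __post_init__(self) -> None:
        self.sequence = normalize(self.sequence)
        if len(self.sequence) < 8:
            raise ValueError(
                f"miRNA {self.mirna_id!r} is shorter than 8 nt; positions 1-8 "
                "are required for seed matching"
            )


def read_fastq(path, phred_offset: int = 33) -> Iterator[SequencedRead]:
    """Stream 4-line FASTQ records as :class:`SequencedRead`.

    Quality characters are decoded as ``ord(c) - phred_offset`` with
    ``phred_offset`` in {33, 64}.  Malformed records raise
    :class:`FastqFormatError` naming the failing record index.
    """
    if phred_offset not in (33, 64):
        raise ValueError(f"phred_offset must be 33 or 64, got {phred_offset}")
    with open(path) as handle:
        it = FastqGeneralIterator(handle)
        index = 0
        while True:
            try:
                title, seq, qual = next(it)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"malformed FASTQ record #{index + 1} in {path}: {exc}"
                ) from exc
            index += 1
            quals = tuple(ord(c) - phred_offset for c in qual)
            if any(q < 0 for q in quals):
                raise FastqFormatError(
                    f"malformed FASTQ record #{index} in {path}: quality "
                    f"character below offset {phred_offset}"
                )
            yield SequencedRead(title.split()[0], seq.upper(), quals)


def write_fastq(reads: Iterable[SequencedRead], path, phred_offset: int = 33) -> None:
    with open(path, "w") as out:
        for read in reads:
            qual = "".join(chr(q + phred_offset) for q in read.quals)
            out.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


def read_fasta(path) -> list[tuple[str, str]]:
    """Parse FASTA into ``(id, sequence)`` pairs, uppercased with U -> T.

    Duplicate ids are rejected (they would make UTR/miRNA lookups ambiguous).
    """
    entries: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seen[record.id] = seen.get(record.id, 0) + 1
        entries.append((record.id, normalize(str(record.seq))))
    duplicates = sorted(name for name, n in seen.items() if n > 1)
    if duplicates:
        raise ValueError(f"duplicate FASTA ids in {path}: {', '.join(duplicates)}")
    return entries


def load_utrs(path, conservation: Optional[dict[str, bool]] = None) -> list[UtrReference]:
    conservation = conservation or {}
    return [
        UtrReference(name, seq, conserved=conservation.get(name))
        for name, seq in read_fasta(path)
    ]


def load_mirnas(path, expression: Optional[dict[str, float]] = None) -> list[MatureMirna]:
    expression = expression or {}
    return [
        MatureMirna(name, seq, expression=expression.get(name))
        for name, seq in read_fasta(path)
    ]


def read_two_column_tsv(path) -> list[tuple[str, str]]:
    rows = []
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(f"{path}: expected 2 tab-separated columns, got {line!r}")
            rows.append((fields[0], fields[1]))
    return rows


def load_expression(path) -> dict[str, float]:
    """mirna_id<TAB>expression -> dict."""
    return {m: float(v) for m, v in read_two_column_tsv(path)}


def load_validated(path) -> set[tuple[str, str]]:
    """mirna_id<TAB>utr_id pairs of experimentally validated interactions."""
    return set(read_two_column_tsv(path))


def load_conservation(path) -> dict[str, bool]:
    """utr_id<TAB>0/1 conservation flags."""
    return {u: bool(int(v)) for u, v in read_two_column_tsv(path)}


def write_site_report(sites: Sequence, path) -> None:
    """Write ranked target sites as TSV with 1-based inclusive coordinates.

    ``sites`` must already be ranked (see ``target_id.rank_mtis``); rows are
    emitted in rank order.
    """
    ordered = sorted(sites, key=lambda s: s.rank)
    with open(path, "w", newline="") as out:
        writer = csv.writer(out, delimiter="\t", lineterminator="\n")
        writer.writerow(SITE_REPORT_COLUMNS)
        for s in ordered:
            writer.writerow(
                [
                    s.utr_id,
                    s.mirna_id,
                    s.site_start + 1,
                    s.site_end,
                    s.seed_match_type,
                    s.cluster_id,
                    s.read_support,
                    f"{s.conversion_read_fraction:.4f}",
                    int(bool(s.validated)),
                    "" if s.expression is None else f"{s.expression:.4f}",
                    s.rank,
                ]
            )
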