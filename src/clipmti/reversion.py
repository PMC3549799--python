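"""C->T reversion mapping for PAR-CLIP reads.

PAR-CLIP's 4SU incorporation leaves a diagnostic T->C substitution in reads
at crosslink positions, which defeats strict low-mismatch alignment.  Rather
than raising the aligner's mismatch allowance (which admits all twelve
substitution types and inflates both runtime and mis-mappings), each read is
expanded into variants in which exactly one C is reverted back to T: a read
with c cytidines yields 1 + c sequences (the original plus one per C).  All
variants are aligned with the ordinary one-mismatch allowance; a read whose
only deviations from the reference are one reverted conversion plus one
further mismatch (conversion or error) therefore still maps.

After alignment the variant hits are reconciled back onto the *original*
read: at each candidate placement the original bases are re-compared with
the reference, read-C-over-reference-T differences are recorded as
conversion events, and only the remaining differences count as mismatches.
A conversion absorbed by the mismatch allowance is thus still reported as a
conversion — it is biological signal, not error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .aligner import MappedRead, RawAlignment, UtrIndex, align
from .io_formats import SequencedRead

__all__ = ["ReadVariant", "expand_c_to_t", "reconcile", "map_read"]


@dataclass(frozen=True)
class ReadVariant:
    """The original read or a single-C->T revert of it."""

    parent: SequencedRead
    variant_bases: str
    reverted_position: Optional[int]  # 0-based index of the reverted C, None = original


def expand_c_to_t(read: SequencedRead) -> list[ReadVariant]:
    """Return the original read plus one variant per cytidine.

    Variants are ordered original-first, then by the reverted C position
    left to right; each variant differs from the parent at exactly that one
    position (C replaced by T).
    """
    variants = [ReadVariant(read, read.bases, None)]
    for i, base in enumerate(read.bases):
        if base == "C":
            variants.append(
                ReadVariant(read, read.bases[:i] + "T" + read.bases[i + 1 :], i)
            )
    return variants


def _evaluate_placement(
    bases: str, ref: str, start: int, parclip: bool
) -> tuple[frozenset[int], frozenset[int]]:
    """Split original-read differences at a placement into (mismatches, conversions)."""
    mismatches, conversions = [], []
    for i, base in enumerate(bases):
        r = ref[start + i]
        if base == r:
            continue
        if parclip and base == "C" and r == "T":
            conversions.append(i)
        else:
            mismatches.append(i)
    return frozenset(mismatches), frozenset(conversions)


def reconcile(
    read: SequencedRead,
    variant_hits: Iterable[tuple[ReadVariant, RawAlignment]],
    sequences: dict[str, str],
    max_mismatch: int = 1,
    parclip: bool = True,
) -> Optional[MappedRead]:
    """Pick one placement for the parent read from its variants' hits.

    Every distinct placement is re-evaluated against the original read
    bases; placements whose non-conversion mismatch count exceeds
    ``max_mismatch`` are dropped.  Ties are broken deterministically:
    fewest mismatches, then most conversions (favouring the crosslink
    interpretation), then smallest (utr_id, start).  Returns None when no
    placement survives (unmapped).
    """
    placements = sorted({(hit.utr_id, hit.start) for _, hit in variant_hits})
    best = None
    best_key = None
    for utr_id, start in placements:
        ref = sequences[utr_id]
        mismatches, conversions = _evaluate_placement(read.bases, ref, start, parclip)
        if len(mismatches) > max_mismatch:
            continue
        key = (len(mismatches), -len(conversions), utr_id, start)
        if best_key is None or key < best_key:
            best_key = key
            best = MappedRead(
                read_id=read.read_id,
                multiplicity=read.multiplicity,
                utr_id=utr_id,
                start=start,
                end=start + len(read.bases),
                mismatch_positions=mismatches,
                conversion_positions=conversions,
            )
    return best


def map_read(
    read: SequencedRead,
    index: UtrIndex,
    max_mismatch: int = 1,
    parclip: bool = True,
) -> Optional[MappedRead]:
    """Align one preprocessed read, with reversion expansion in PAR-CLIP mode.

    CLIP mode aligns the original sequence only and reports no conversion
    positions (every difference is a plain mismatch).
    """
    if parclip:
        variants = expand_c_to_t(read)
        # identical variant sequences can arise when the read has repeated
        # context; alignment results depend only on the sequence, so dedup
        seen: set[str] = set()
        hits: list[tuple[ReadVariant, RawAlignment]] = []
        for variant in variants:
            if variant.variant_bases in seen:
                continue
            seen.add(variant.variant_bases)
            for hit in align(variant.variant_bases, index, max_mismatch):
                hits.append((variant, hit))
        return reconcile(read, hits, index.sequences, max_mismatch, parclip=True)
    hits = [(ReadVariant(read, read.bases, None), h) for h in align(read.bases, index, max_mismatch)]
    return reconcile(read, hits, index.sequences, max_mismatch, parclip=False)
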