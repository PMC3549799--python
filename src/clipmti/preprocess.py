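"""Read preprocessing: 3' adapter trimming, 3' quality trimming, length and
ambiguity filtering, and duplicate collapsing.

The rules are deliberately simple and single-end:

* the 3' adapter is cut at the leftmost position where the adapter prefix
  aligns to the read suffix with sufficient overlap and a bounded mismatch
  rate;
* trailing bases are stripped while the terminal phred score is below the
  threshold (a strip-while loop, not BWA-style sum trimming);
* reads shorter than ``min_length`` after either trim, or containing an
  ambiguous base (N) after adapter trimming, are discarded;
* identical surviving sequences are collapsed into one record carrying a
  multiplicity count, so downstream alignment maps each distinct sequence
  once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .io_formats import SequencedRead

__all__ = ["PreprocessParams", "trim_adapter", "quality_trim", "collapse_reads", "preprocess_reads"]


@dataclass
class PreprocessParams:
    """Tunable thresholds for Steps 1-2.

    ``min_length`` (15 nt) and ``qual_threshold`` (phred 20) are the
    pipeline's canonical filter values; the adapter-matching tolerances are
    exposed because adapter chemistry varies between libraries.
    """

    adapter: str = ""
    min_length: int = 15
    qual_threshold: int = 20
    min_adapter_overlap: int = 5
    max_adapter_mismatch_rate: float = 0.1

    def __post_init__(self) -> None:
        self.adapter = self.adapter.upper()
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.qual_threshold < 0:
            raise ValueError("qual_threshold must be >= 0")


def _adapter_match_at(bases: str, adapter: str, pos: int, max_rate: float) -> bool:
    """Does the adapter prefix match the read suffix starting at ``pos``?"""
    overlap = min(len(bases) - pos, len(adapter))
    allowed = int(max_rate * overlap)
    mismatches = 0
    for i in range(overlap):
        if bases[pos + i] != adapter[i]:
            mismatches += 1
            if mismatches > allowed:
                return False
    return True


def trim_adapter(read: SequencedRead, params: PreprocessParams) -> Optional[SequencedRead]:
    """Cut the read at the leftmost 3' adapter occurrence; None = discard.

    Discards when the trimmed read is shorter than ``min_length`` or still
    contains an N.  An empty adapter makes trimming a no-op (the filters
    still apply).
    """
    bases, quals = read.bases, read.quals
    adapter = params.adapter
    if adapter:
        cut = None
        last_start = len(bases) - params.min_adapter_overlap
        for pos in range(0, last_start + 1):
            if _adapter_match_at(bases, adapter, pos, params.max_adapter_mismatch_rate):
                cut = pos
                break
        if cut is not None:
            bases, quals = bases[:cut], quals[:cut]
    if len(bases) < params.min_length or "N" in bases:
        return None
    return SequencedRead(read.read_id, bases, quals, read.multiplicity)


def quality_trim(read: SequencedRead, params: PreprocessParams) -> Optional[SequencedRead]:
    """Strip 3' bases while the terminal phred score is below threshold."""
    end = len(read.bases)
    while end > 0 and read.quals[end - 1] < params.qual_threshold:
        end -= 1
    if end < params.min_length:
        return None
    if end == len(read.bases):
        return read
    return SequencedRead(read.read_id, read.bases[:end], read.quals[:end], read.multiplicity)


def collapse_reads(reads: Iterable[SequencedRead]) -> list[SequencedRead]:
    """Merge reads with identical base strings into one record.

    The representative keeps the first-seen id and quality string; the
    multiplicity is the sum over merged reads, so raw read counts are
    conserved (Σ multiplicity == number of inputs when inputs are raw).
    """
    by_bases: dict[str, SequencedRead] = {}
    for read in reads:
        rep = by_bases.get(read.bases)
        if rep is None:
            by_bases[read.bases] = SequencedRead(
                read.read_id, read.bases, read.quals, read.multiplicity
            )
        else:
            rep.multiplicity += read.multiplicity
    return list(by_bases.values())


def preprocess_reads(
    reads: Iterable[SequencedRead], params: PreprocessParams
) -> tuple[list[SequencedRead], dict[str, int]]:
    """Run adapter trimming, quality trimming and collapsing over a stream.

    Returns the collapsed reads and a counter dict (raw-read units):
    ``reads_in``, ``discarded_adapter``, ``discarded_quality``, ``surviving``,
    ``unique_sequences``.
    """
    counts = {"reads_in": 0, "discarded_adapter": 0, "discarded_quality": 0}
    survivors = []
    for read in reads:
        counts["reads_in"] += read.multiplicity
        trimmed = trim_adapter(read, params)
        if trimmed is None:
            counts["discarded_adapter"] += read.multiplicity
            continue
        trimmed = quality_trim(trimmed, params)
        if trimmed is None:
            counts["discarded_quality"] += read.multiplicity
            continue
        survivors.append(trimmed)
    collapsed = collapse_reads(survivors)
    counts["surviving"] = sum(r.multiplicity for r in collapsed)
    counts["unique_sequences"] = len(collapsed)
    return collapsed, counts
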