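"""Grouping mapped reads into clusters on each UTR and filtering them.

Clusters are single-linkage components of the interval-overlap graph: two
reads belong together when their mapped spans overlap by at least
``min_overlap`` nucleotides (default 1), and overlap chains are merged even
when the chain ends do not themselves overlap.  A cluster survives filtering
when it holds at least ``min_reads`` reads (default 5, counted in raw-read
units via collapsed multiplicities) and — in PAR-CLIP mode only — when at
least ``min_conversion_fraction`` (default 20%) of its reads carry a T->C
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .aligner import MappedRead
from .io_formats import UtrReference

__all__ = ["ClusterParams", "ReadCluster", "build_clusters", "filter_clusters", "write_cluster_bed"]


@dataclass
class ClusterParams:
    min_reads: int = 5
    min_conversion_fraction: float = 0.20
    min_overlap: int = 1

    def __post_init__(self) -> None:
        if self.min_reads < 1:
            raise ValueError("min_reads must be >= 1")
        if not 0.0 <= self.min_conversion_fraction <= 1.0:
            raise ValueError("min_conversion_fraction must be in [0, 1]")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


@dataclass
class ReadCluster:
    """A maximal set of overlapping mapped reads on one UTR.

    ``per_base_conversion`` maps each UTR position holding a reference T
    within the span to ``(converted_read_count, covering_read_count)``,
    multiplicity-weighted; ``conversion_read_fraction`` is the weighted
    fraction of member reads with at least one conversion.
    """

    cluster_id: str
    utr_id: str
    span_start: int
    span_end: int
    members: list[MappedRead]
    read_support: int
    conversion_read_fraction: float
    per_base_conversion: dict[int, tuple[int, int]] = field(default_factory=dict, repr=False)


def _summarize(
    cluster_id: str, utr_id: str, members: list[MappedRead], utr_seq: str
) -> ReadCluster:
    span_start = min(m.start for m in members)
    span_end = max(m.end for m in members)
    support = sum(m.multiplicity for m in members)
    converted_support = sum(m.multiplicity for m in members if m.conversion_positions)
    per_base: dict[int, tuple[int, int]] = {}
    for pos in range(span_start, span_end):
        if utr_seq[pos] != "T":
            continue
        covering = converted = 0
        for m in members:
            if m.start <= pos < m.end:
                covering += m.multiplicity
                if (pos - m.start) in m.conversion_positions:
                    converted += m.multiplicity
        if covering:
            per_base[pos] = (converted, covering)
    return ReadCluster(
        cluster_id=cluster_id,
        utr_id=utr_id,
        span_start=span_start,
        span_end=span_end,
        members=members,
        read_support=support,
        conversion_read_fraction=converted_support / support,
        per_base_conversion=per_base,
    )


def build_clusters(
    mapped: Iterable[MappedRead],
    utrs: Iterable[UtrReference],
    params: ClusterParams = ClusterParams(),
) -> list[ReadCluster]:
    """Single-linkage interval clustering per UTR.

    Every mapped read lands in exactly one cluster; clusters are sorted by
    (utr_id, span_start) and given deterministic sequential ids.
    """
    seq_by_id = {u.utr_id: u.sequence for u in utrs}
    by_utr: dict[str, list[MappedRead]] = {}
    for m in mapped:
        by_utr.setdefault(m.utr_id, []).append(m)

    clusters: list[ReadCluster] = []
    for utr_id in sorted(by_utr):
        reads = sorted(by_utr[utr_id], key=lambda m: (m.start, m.end, m.read_id))
        component: list[MappedRead] = []
        comp_end = -1
        for m in reads:
            # overlap >= min_overlap with the growing component's hull
            if component and m.start <= comp_end - params.min_overlap:
                component.append(m)
                comp_end = max(comp_end, m.end)
            else:
                if component:
                    clusters.append(_summarize("", utr_id, component, seq_by_id[utr_id]))
                component = [m]
                comp_end = m.end
        if component:
            clusters.append(_summarize("", utr_id, component, seq_by_id[utr_id]))

    clusters.sort(key=lambda c: (c.utr_id, c.span_start))
    for i, c in enumerate(clusters, start=1):
        c.cluster_id = f"cluster{i:05d}"
    return clusters


def filter_clusters(
    clusters: Iterable[ReadCluster],
    params: ClusterParams = ClusterParams(),
    parclip_mode: bool = True,
) -> list[ReadCluster]:
    """Apply the read-support and (PAR-CLIP only) conversion-fraction filters."""
    kept = []
    for c in clusters:
        if c.read_support < params.min_reads:
            continue
        if parclip_mode and c.conversion_read_fraction < params.min_conversion_fraction:
            continue
        kept.append(c)
    return kept


def write_cluster_bed(clusters: Iterable[ReadCluster], path) -> None:
    """BED (0-based half-open) of cluster spans; score = read support."""
    with open(path, "w") as out:
        for c in clusters:
            out.write(
                f"{c.utr_id}\t{c.span_start}\t{c.span_end}\t{c.cluster_id}\t{c.read_support}\t+\n"
            )
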