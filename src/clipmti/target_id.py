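"""Seed-match scanning inside read clusters and evidence-based ranking.

A target site is the Watson-Crick complement of the miRNA seed on the mRNA
3'UTR.  With the miRNA written 5'->3' and the UTR 5'->3', the complement of
miRNA positions 2-8 appears reverse-complemented on the UTR, and the UTR
base pairing miRNA position 1 sits immediately 3' of it.  The three
canonical site types are

* ``8mer``    — perfect match to miRNA positions 2-8 and an A opposite
  position 1 (site length 8);
* ``7mer-m8`` — perfect match to positions 2-8, position-1 base not A
  (site length 7);
* ``7mer-A1`` — perfect match to positions 2-7 plus the position-1 A,
  without extending to a match at position 8 (site length 7).

Types are exclusive and maximal: an 8mer is never additionally reported as
a 7mer.  G:U wobble pairs are not allowed.

Ranking follows the evidence hierarchy: experimentally validated
interactions first, then miRNA expression, then seed strength
(8mer > 7mer-m8 > 7mer-A1), then cluster read support, with positional
tie-breaks so ranks are a deterministic permutation 1..n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from ._dna import revcomp
from .clustering import ReadCluster
from .io_formats import MatureMirna, UtrReference

__all__ = ["TargetSite", "SEED_TYPES", "find_seed_matches", "rank_mtis", "site_anchor"]

SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_TYPE_STRENGTH = {"8mer": 0, "7mer-m8": 1, "7mer-A1": 2}


@dataclass
class TargetSite:
    """A seed-match hit inside a cluster; coordinates are 0-based half-open
    on the UTR and cover the seed-paired bases plus, for A1 types, the
    position-1 A."""

    utr_id: str
    cluster_id: str
    site_start: int
    site_end: int
    mirna_id: str
    seed_match_type: str
    read_support: int = 0
    conversion_read_fraction: float = 0.0
    validated: bool = False
    expression: Optional[float] = None
    rank: Optional[int] = None

    def __post_init__(self) -> None:
        if self.seed_match_type not in _TYPE_STRENGTH:
            raise ValueError(f"unknown seed match type {self.seed_match_type!r}")
        expected = 8 if self.seed_match_type == "8mer" else 7
        if self.site_end - self.site_start != expected:
            raise ValueError(
                f"{self.seed_match_type} site must span {expected} nt, "
                f"got {self.site_end - self.site_start}"
            )


def site_anchor(site: TargetSite) -> int:
    """UTR coordinate of the base pairing miRNA position 1.

    For 8mer and 7mer-A1 sites this is the site's 3'-most base (the A);
    7mer-m8 sites span positions 2-8 only, so the anchor is the base just
    3' of the site (which may equal the UTR length at the edge).
    """
    if site.seed_match_type == "7mer-m8":
        return site.site_end
    return site.site_end - 1


def find_seed_matches(
    cluster: ReadCluster,
    utr: UtrReference,
    mirnas: Iterable[MatureMirna],
    flank: int = 0,
) -> list[TargetSite]:
    """Scan the cluster span (± flank) of a UTR for seed-complementary sites.

    Each hit is reported once with its most specific type.  Crosslink sites
    sit near rather than on seeds, so ``flank`` extends the scanned window
    beyond the cluster span when needed.
    """
    seq = utr.sequence
    lo = max(0, cluster.span_start - flank)
    hi = min(len(seq), cluster.span_end + flank)
    sites: list[TargetSite] = []
    for mirna in mirnas:
        m = mirna.sequence
        seed7 = revcomp(m[1:8])  # complement of positions 2-8, mRNA 5'->3'
        seed6 = revcomp(m[1:7])  # complement of positions 2-7
        # positions 2-8 matches: classify by the position-1 base (3'-adjacent)
        m8_starts = set()
        i = seq.find(seed7, lo)
        while i != -1 and i + 7 <= hi:
            m8_starts.add(i)
            if i + 7 < len(seq) and seq[i + 7] == "A" and i + 8 <= hi:
                sites.append(
                    TargetSite(utr.utr_id, cluster.cluster_id, i, i + 8, mirna.mirna_id, "8mer")
                )
            else:
                sites.append(
                    TargetSite(utr.utr_id, cluster.cluster_id, i, i + 7, mirna.mirna_id, "7mer-m8")
                )
            i = seq.find(seed7, i + 1)
        # positions 2-7 + A matches that do not extend to position 8
        i = seq.find(seed6, lo)
        while i != -1 and i + 7 <= hi:
            extends_to_m8 = i >= 1 and seq[i - 1] == seed7[0]
            if seq[i + 6] == "A" and not extends_to_m8:
                sites.append(
                    TargetSite(utr.utr_id, cluster.cluster_id, i, i + 7, mirna.mirna_id, "7mer-A1")
                )
            i = seq.find(seed6, i + 1)
    for s in sites:
        s.read_support = cluster.read_support
        s.conversion_read_fraction = cluster.conversion_read_fraction
    sites.sort(key=lambda s: (s.site_start, _TYPE_STRENGTH[s.seed_match_type], s.mirna_id))
    return sites


def rank_mtis(
    sites: list[TargetSite],
    validated: Optional[set[tuple[str, str]]] = None,
    expression: Optional[dict[str, float]] = None,
) -> list[TargetSite]:
    """Annotate and rank sites; returns a new list sorted by rank 1..n.

    Sort order: validated first, then expression (missing treated as -inf),
    then seed strength, then cluster read support, then (utr_id, site_start,
    mirna_id) for determinism.
    """
    validated = validated or set()
    expression = expression or {}
    for s in sites:
        s.validated = (s.mirna_id, s.utr_id) in validated
        s.expression = expression.get(s.mirna_id, s.expression)

    def key(s: TargetSite):
        expr = s.expression if s.expression is not None else -math.inf
        return (
            0 if s.validated else 1,
            -expr,
            _TYPE_STRENGTH[s.seed_match_type],
            -s.read_support,
            s.utr_id,
            s.site_start,
            s.mirna_id,
        )

    ranked = sorted(sites, key=key)
    for rank, s in enumerate(ranked, start=1):
        s.rank = rank
    return ranked
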