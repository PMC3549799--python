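"""Seed-match classification and evidence ranking."""

import numpy as np
import pytest

from clipmti._dna import revcomp
from clipmti.clustering import ClusterParams, build_clusters
from clipmti.aligner import MappedRead
from clipmti.io_formats import MatureMirna, UtrReference
from clipmti.target_id import TargetSite, find_seed_matches, rank_mtis

# seed (positions 2-8) of 5'-UAAGGCACG...-3' is AAGGCAC; its complement on
# the mRNA read 5'->3' is GTGCCTT
MIRNA = MatureMirna("mir-x", "UAAGGCACGUACGUACGUACGU")
SEED7_RC = "GTGCCTT"
assert revcomp("AAGGCAC") == SEED7_RC


def cluster_over(utr, start, end):
    reads = [
        MappedRead(read_id=f"r{i}", multiplicity=1, utr_id=utr.utr_id, start=start, end=end)
        for i in range(6)
    ]
    (cluster,) = build_clusters(reads, [utr], ClusterParams())
    return cluster


def embed(motif, flank_left="GATAGATTAGGATTAG", flank_right="GGATTAGGATTAGGAT"):
    utr = UtrReference("u1", flank_left + motif + flank_right)
    return utr, len(flank_left)


class TestSeedMatchClassification:
    def test_8mer(self):
        utr, offset = embed(SEED7_RC + "A")
        cluster = cluster_over(utr, offset - 4, offset + 12)
        (site,) = find_seed_matches(cluster, utr, [MIRNA])
        assert site.seed_match_type == "8mer"
        assert (site.site_start, site.site_end) == (offset, offset + 8)

    def test_7mer_m8_when_position_one_not_a(self):
        utr, offset = embed(SEED7_RC + "G")
        cluster = cluster_over(utr, offset - 4, offset + 12)
        (site,) = find_seed_matches(cluster, utr, [MIRNA])
        assert site.seed_match_type == "7mer-m8"
        assert (site.site_start, site.site_end) == (offset, offset + 7)

    def test_7mer_a1_without_m8_extension(self):
        # complement of positions 2-7 plus A, preceded by a base that does
        # not pair miRNA position 8
        utr, offset = embed("C" + SEED7_RC[1:] + "A")  # first base != G breaks m8
        cluster = cluster_over(utr, offset - 4, offset + 12)
        (site,) = find_seed_matches(cluster, utr, [MIRNA])
        assert site.seed_match_type == "7mer-A1"
        assert (site.site_start, site.site_end) == (offset + 1, offset + 8)

    def test_types_are_exclusive(self):
        # an 8mer region must not additionally be reported as 7mer
        utr, offset = embed(SEED7_RC + "A")
        cluster = cluster_over(utr, offset - 4, offset + 12)
        sites = find_seed_matches(cluster, utr, [MIRNA])
        assert len(sites) == 1

    def test_no_complementarity_no_sites(self):
        utr, offset = embed("GATTAGGATAGG")
        cluster = cluster_over(utr, offset - 4, offset + 10)
        assert find_seed_matches(cluster, utr, [MIRNA]) == []

    def test_site_must_lie_in_window_without_flank(self):
        utr, offset = embed(SEED7_RC + "A")
        cluster = cluster_over(utr, 0, offset + 4)  # window cuts the site
        assert find_seed_matches(cluster, utr, [MIRNA], flank=0) == []
        assert len(find_seed_matches(cluster, utr, [MIRNA], flank=10)) == 1

    def test_reported_sites_verify_against_brute_force(self, default_dataset):
        """Every site reported on simulated clusters passes an independent
        reverse-complement re-check of the seed definition."""
        utrs, mirnas, truth, _ = default_dataset
        mirna_by_id = {m.mirna_id: m for m in mirnas}
        for utr in utrs[:10]:
            reads = [
                MappedRead(read_id=f"r{s}", multiplicity=1, utr_id=utr.utr_id,
                           start=s, end=min(s + 40, len(utr.sequence)))
                for s in range(0, len(utr.sequence) - 40, 35)
            ]
            clusters = build_clusters(reads, [utr], ClusterParams())
            for cluster in clusters:
                for site in find_seed_matches(cluster, utr, mirnas):
                    m = mirna_by_id[site.mirna_id].sequence
                    span = utr.sequence[site.site_start : site.site_end]
                    if site.seed_match_type == "8mer":
                        assert span == revcomp(m[1:8]) + "A"
                    elif site.seed_match_type == "7mer-m8":
                        assert span == revcomp(m[1:8])
                        anchor = site.site_end
                        assert anchor >= len(utr.sequence) or utr.sequence[anchor] != "A"
                    else:
                        assert span == revcomp(m[1:7]) + "A"
                        assert site.site_start == 0 or (
                            utr.sequence[site.site_start - 1] != revcomp(m[1:8])[0]
                        )


class TestRankMtis:
    def _site(self, utr="u1", start=100, stype="7mer-m8", mirna="mir-a", support=10):
        end = start + (8 if stype == "8mer" else 7)
        return TargetSite(utr, "cluster00001", start, end, mirna, stype, read_support=support)

    def test_validated_beats_expression(self):
        s1 = self._site(mirna="mir-a")
        s2 = self._site(mirna="mir-b", start=200)
        ranked = rank_mtis([s1, s2], validated={("mir-a", "u1")}, expression={"mir-b": 1000.0})
        assert ranked[0].mirna_id == "mir-a" and ranked[0].rank == 1

    def test_expression_orders_unvalidated(self):
        s1 = self._site(mirna="mir-a")
        s2 = self._site(mirna="mir-b", start=200)
        ranked = rank_mtis([s1, s2], expression={"mir-a": 10.0, "mir-b": 100.0})
        assert [s.mirna_id for s in ranked] == ["mir-b", "mir-a"]

    def test_missing_expression_sorts_last(self):
        s1 = self._site(mirna="mir-a")
        s2 = self._site(mirna="mir-b", start=200)
        ranked = rank_mtis([s1, s2], expression={"mir-b": 0.001})
        assert [s.mirna_id for s in ranked] == ["mir-b", "mir-a"]

    def test_seed_strength_breaks_expression_ties(self):
        weak = self._site(stype="7mer-A1", start=100)
        strong = self._site(stype="8mer", start=200)
        ranked = rank_mtis([weak, strong])
        assert [s.seed_match_type for s in ranked] == ["8mer", "7mer-A1"]

    def test_full_ties_fall_back_to_position(self):
        s1 = self._site(start=300)
        s2 = self._site(start=100)
        ranked = rank_mtis([s1, s2])
        assert [s.site_start for s in ranked] == [100, 300]

    def test_ranks_are_a_permutation(self):
        rng = np.random.default_rng(3)
        sites = [
            self._site(
                utr=f"u{rng.integers(3)}",
                start=int(rng.integers(50, 400)),
                stype=["8mer", "7mer-m8", "7mer-A1"][int(rng.integers(3))],
                mirna=f"mir-{rng.integers(4)}",
                support=int(rng.integers(5, 50)),
            )
            for _ in range(25)
        ]
        ranked = rank_mtis(sites, validated={("mir-1", "u0")}, expression={"mir-2": 5.0})
        assert sorted(s.rank for s in ranked) == list(range(1, 26))
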