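"""Positional conversion profiles, the region t-test, and stratification."""

import numpy as np
import pandas as pd
import pytest

from clipmti.aligner import MappedRead
from clipmti.clustering import ClusterParams, build_clusters
from clipmti.conversion_stats import (
    DEFAULT_STRATA,
    ConversionProfile,
    InsufficientDataError,
    StratumLabel,
    region_ttest,
    site_conversion_profile,
    stratified_tests,
)
from clipmti.io_formats import UtrReference
from clipmti.target_id import TargetSite


class TestProfileArithmetic:
    def _single_site_setup(self):
        # anchor at coordinate 30 (8mer site [23, 31)); position 9 -> coord 22
        seq = list("GAGAGAGAGA" * 6)
        seq[22] = "T"
        utr = UtrReference("u1", "".join(seq))
        site = TargetSite("u1", "cluster00001", 23, 31, "mir-a", "8mer")
        reads = [
            MappedRead(read_id=f"r{i}", multiplicity=1, utr_id="u1", start=10, end=40,
                       conversion_positions=frozenset({12} if i < 6 else ()))
            for i in range(10)
        ]
        (cluster,) = build_clusters(reads, [utr], ClusterParams())
        return site, cluster, utr

    def test_single_position_ratio(self):
        site, cluster, utr = self._single_site_setup()
        profile = site_conversion_profile([site], {cluster.cluster_id: cluster}, {"u1": utr})
        # position 9 = anchor - 8 = coord 22, covered by 10 reads, 6 converted
        assert profile.covering[8] == 10
        assert profile.converted[8] == 6
        assert profile.ratio[8] == pytest.approx(0.6)

    def test_non_t_positions_are_nan(self):
        site, cluster, utr = self._single_site_setup()
        profile = site_conversion_profile([site], {cluster.cluster_id: cluster}, {"u1": utr})
        # coord 30 (position 1) is the site's final A -> undefined
        assert np.isnan(profile.ratio[0])

    def test_no_sites_gives_all_nan(self):
        profile = site_conversion_profile([], {}, {})
        assert profile.n_positions == 14
        assert np.all(np.isnan(profile.ratio))

    def test_counts_invariant(self):
        with pytest.raises(ValueError):
            ConversionProfile(converted=[5], covering=[4])


class TestRegionTtest:
    def test_symmetric_null_gives_half(self):
        profile = ConversionProfile(
            converted=[5] * 14, covering=[10] * 14
        )
        t, p = region_ttest(profile)
        assert t == 0.0
        assert p == pytest.approx(0.5)

    def test_strong_effect_frozen_values(self):
        # per-position ratios constructed exactly; expected t and p frozen
        # from the closed-form pooled-variance formula and the t CDF
        b = [0.4, 0.45, 0.5, 0.42, 0.47, 0.44, 0.41]
        a = [0.05, 0.04, 0.06, 0.05, 0.03, 0.06, 0.04]
        covering = [100] * 14
        converted = [int(round(x * 100)) for x in a + b]
        profile = ConversionProfile(converted=converted, covering=covering)
        t, p = region_ttest(profile)
        assert t == pytest.approx(28.169132042006552, rel=1e-9)
        assert p == pytest.approx(1.241007296926e-12, rel=1e-6)
        assert p < 0.001

    def test_swapped_regions_complementary(self):
        b = [0.4, 0.45, 0.5, 0.42, 0.47, 0.44, 0.41]
        a = [0.05, 0.04, 0.06, 0.05, 0.03, 0.06, 0.04]
        converted = [int(round(x * 100)) for x in b + a]  # effect reversed
        profile = ConversionProfile(converted=converted, covering=[100] * 14)
        t, p = region_ttest(profile)
        assert t < 0
        assert p > 0.999

    def test_insufficient_positions_flagged(self):
        covering = [10] * 3 + [0] * 11  # only positions 1-3 defined
        converted = [5, 5, 5] + [0] * 11
        profile = ConversionProfile(converted=converted, covering=covering)
        with pytest.raises(InsufficientDataError):
            region_ttest(profile)


class TestStratumLabel:
    @pytest.mark.parametrize("label", ["CN78", "CN8", "CN7", "C78", "C8", "C7", "N78", "N8", "N7"])
    def test_parse_render_roundtrip(self, label):
        assert str(StratumLabel.parse(label)) == label

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            StratumLabel(frozenset(), frozenset({7}))


class TestStratifiedTests:
    def _setup(self, rng):
        """Two UTRs (one conserved), 8mer site on each, distinct rates."""
        utrs, clusters, sites = {}, {}, []
        for idx, (utr_id, conserved, rate) in enumerate(
            [("u1", True, 0.5), ("u2", False, 0.5)]
        ):
            seq = list("".join(rng.choice(list("ACGT"), size=80)))
            for c in range(14, 31):
                seq[c] = "T"  # make every profile position defined
            utr = UtrReference(utr_id, "".join(seq), conserved=conserved)
            site = TargetSite(utr_id, f"cluster0000{idx + 1}", 23, 31, "mir-a", "8mer")
            reads = [
                MappedRead(
                    read_id=f"{utr_id}_r{i}", multiplicity=1, utr_id=utr_id,
                    start=5, end=45,
                    conversion_positions=frozenset(
                        c - 5 for c in range(14, 31) if rng.random() < rate
                    ),
                )
                for i in range(12)
            ]
            (cluster,) = build_clusters(reads, [utr], ClusterParams())
            cluster.cluster_id = site.cluster_id
            utrs[utr_id] = utr
            clusters[site.cluster_id] = cluster
            sites.append(site)
        return utrs, clusters, sites

    def test_identity_stratum_equals_unrestricted(self):
        rng = np.random.default_rng(5)
        utrs, clusters, sites = self._setup(rng)
        table = stratified_tests(sites, clusters, utrs, [StratumLabel.parse("CN8")])
        profile = site_conversion_profile(sites, clusters, utrs)
        t, p = region_ttest(profile)
        assert table.loc[0, "n_sites"] == 2
        assert table.loc[0, "p"] == pytest.approx(p)
        assert table.loc[0, "t"] == pytest.approx(t)

    def test_conservation_restriction_selects_sites(self):
        rng = np.random.default_rng(5)
        utrs, clusters, sites = self._setup(rng)
        table = stratified_tests(
            sites, clusters, utrs,
            [StratumLabel.parse("C8"), StratumLabel.parse("N8"), StratumLabel.parse("CN7")],
        )
        assert list(table["n_sites"]) == [1, 1, 0]
        assert np.isnan(table.loc[2, "p"])  # empty stratum -> NA row

    def test_top_mirna_restriction(self):
        rng = np.random.default_rng(5)
        utrs, clusters, sites = self._setup(rng)
        all_m = stratified_tests(sites, clusters, utrs, [StratumLabel.parse("CN8")],
                                 top_mirnas={"mir-a"})
        none_m = stratified_tests(sites, clusters, utrs, [StratumLabel.parse("CN8")],
                                  top_mirnas={"mir-z"})
        unrestricted = stratified_tests(sites, clusters, utrs, [StratumLabel.parse("CN8")])
        assert all_m.loc[0, "p"] == pytest.approx(unrestricted.loc[0, "p"], nan_ok=True)
        assert none_m.loc[0, "n_sites"] == 0

    def test_denominators_monotone_under_restriction(self):
        rng = np.random.default_rng(5)
        utrs, clusters, sites = self._setup(rng)
        full = site_conversion_profile(sites, clusters, utrs)
        conserved_only = site_conversion_profile(sites[:1], clusters, utrs)
        assert np.all(conserved_only.covering <= full.covering)

    def test_stratum_specific_effect_detected(self):
        """Elevated effector conversion only in conserved-8mer sites gives a
        small p for C8 and a null-like p for the untouched stratum."""
        rng = np.random.default_rng(11)
        utrs, clusters, sites = {}, {}, []
        specs = [("u1", True, "8mer", 0.45, 0.05), ("u2", False, "7mer-m8", 0.05, 0.05)]
        for idx, (utr_id, conserved, stype, rate_b, rate_a) in enumerate(specs):
            seq = list("".join(rng.choice(list("ACGT"), size=80)))
            for c in range(14, 31):
                seq[c] = "T"
            utr = UtrReference(utr_id, "".join(seq), conserved=conserved)
            end = 31 if stype == "8mer" else 30
            site = TargetSite(utr_id, f"cluster0000{idx + 1}", 23, end, "mir-a", stype)
            anchor = 30
            effector = set(range(anchor - 13, anchor - 6))
            reads = []
            for i in range(40):
                conv = {
                    c - 5
                    for c in range(14, 31)
                    if rng.random() < (rate_b if c in effector else rate_a)
                }
                reads.append(
                    MappedRead(read_id=f"{utr_id}_r{i}", multiplicity=1, utr_id=utr_id,
                               start=5, end=45, conversion_positions=frozenset(conv))
                )
            (cluster,) = build_clusters(reads, [utr], ClusterParams())
            cluster.cluster_id = site.cluster_id
            utrs[utr_id] = utr
            clusters[site.cluster_id] = cluster
            sites.append(site)
        table = stratified_tests(
            sites, clusters, utrs, [StratumLabel.parse("C8"), StratumLabel.parse("N7")]
        )
        assert table.loc[0, "p"] < 0.01
        assert table.loc[1, "p"] > 0.05
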