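"""Positional T->C conversion statistics over identified target sites.

PAR-CLIP crosslink-induced conversions concentrate in the target-site
region pairing miRNA positions 8-14, just 3' of the seed on the miRNA and
outside seed complementarity, while the seed-paired region (positions 1-7)
stays near background.  This module pools per-position conversion ratios
over sites, compares the two regions with a one-tailed two-sample Student's
t-test, and stratifies the comparison by UTR conservation and seed-match
length, optionally restricting to the most highly expressed miRNAs.

Position k of a site is the UTR nucleotide pairing miRNA position k:
position 1 is the anchor (the A of an 8mer/7mer-A1 site, or the base just
3' of a 7mer-m8 site) and positions increase toward the mRNA 5' side.
Positions whose UTR base is not T carry no information and are excluded
(NaN), not imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import ReadCluster
from .io_formats import UtrReference
from .target_id import TargetSite, site_anchor

__all__ = [
    "ConversionProfile",
    "StratumLabel",
    "DEFAULT_STRATA",
    "InsufficientDataError",
    "site_conversion_profile",
    "region_ttest",
    "stratified_tests",
]

SEED_REGION = tuple(range(1, 8))  # positions pairing miRNA 1-7
EFFECTOR_REGION = tuple(range(8, 15))  # positions pairing miRNA 8-14


class InsufficientDataError(ValueError):
    """A region has fewer than two positions with defined conversion ratios."""


@dataclass
class ConversionProfile:
    """Pooled per-position conversion counts over a set of sites.

    ``converted[k-1]`` / ``covering[k-1]`` hold the pooled read counts at
    position k (1-based, 1..P); ``ratio`` is NaN where nothing covers a T.
    """

    converted: np.ndarray
    covering: np.ndarray

    def __post_init__(self) -> None:
        self.converted = np.asarray(self.converted, dtype=np.int64)
        self.covering = np.asarray(self.covering, dtype=np.int64)
        if self.converted.shape != self.covering.shape:
            raise ValueError("converted and covering must have equal length")
        if np.any(self.converted > self.covering):
            raise ValueError("converted counts cannot exceed covering counts")

    @property
    def n_positions(self) -> int:
        return len(self.converted)

    @property
    def positions(self) -> np.ndarray:
        return np.arange(1, self.n_positions + 1)

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.covering > 0, self.converted / np.maximum(self.covering, 1), np.nan
            )

    def region_ratios(self, region: Sequence[int]) -> np.ndarray:
        """Defined (non-NaN) ratios at the given 1-based positions."""
        r = self.ratio
        vals = [r[k - 1] for k in region if k <= self.n_positions]
        return np.array([v for v in vals if not np.isnan(v)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "converted": self.converted,
                "covering": self.covering,
                "ratio": self.ratio,
            }
        )


@dataclass(frozen=True)
class StratumLabel:
    """Conservation / seed-length stratum, rendered e.g. "CN78", "C7", "N8".

    C = conserved UTRs, N = nonconserved; 7 = 7mer site types, 8 = 8mer.
    """

    conservation: frozenset[str]
    seed_lengths: frozenset[int]

    def __post_init__(self) -> None:
        if not self.conservation or not self.conservation <= {"C", "N"}:
            raise ValueError("conservation must be a non-empty subset of {C, N}")
        if not self.seed_lengths or not self.seed_lengths <= {7, 8}:
            raise ValueError("seed_lengths must be a non-empty subset of {7, 8}")

    def __str__(self) -> str:
        cons = "".join(c for c in "CN" if c in self.conservation)
        lens = "".join(str(n) for n in (7, 8) if n in self.seed_lengths)
        return cons + lens

    @classmethod
    def parse(cls, label: str) -> "StratumLabel":
        cons = frozenset(c for c in label if c in "CN")
        lens = frozenset(int(c) for c in label if c in "78")
        return cls(cons, lens)


DEFAULT_STRATA = tuple(
    StratumLabel.parse(s) for s in ("CN78", "CN8", "CN7", "C78", "C8", "C7", "N78", "N8", "N7")
)


def site_conversion_profile(
    sites: Iterable[TargetSite],
    clusters: dict[str, ReadCluster],
    utrs: dict[str, UtrReference],
    P: int = 14,
) -> ConversionProfile:
    """Pool per-position conversion counts over sites.

    For each site, position k (1..P) maps to UTR coordinate
    ``anchor - (k - 1)``; at coordinates holding a reference T, the site's
    cluster contributes its (converted, covering) read counts there.
    """
    converted = np.zeros(P, dtype=np.int64)
    covering = np.zeros(P, dtype=np.int64)
    for site in sites:
        cluster = clusters[site.cluster_id]
        seq = utrs[site.utr_id].sequence
        anchor = site_anchor(site)
        for k in range(1, P + 1):
            coord = anchor - (k - 1)
            if not (0 <= coord < len(seq)) or seq[coord] != "T":
                continue
            conv, cov = cluster.per_base_conversion.get(coord, (0, 0))
            converted[k - 1] += conv
            covering[k - 1] += cov
    return ConversionProfile(converted, covering)


def region_ttest(
    profile: ConversionProfile,
    region_a: Sequence[int] = SEED_REGION,
    region_b: Sequence[int] = EFFECTOR_REGION,
) -> tuple[float, float]:
    """One-tailed two-sample Student's t-test of region_b > region_a.

    The samples are the per-position pooled conversion ratios (7 values per
    region when all positions are defined); equal variances are assumed.
    Degenerate zero-variance inputs follow the limit convention: equal
    means give (0, 0.5); unequal means give (±inf, 0 or 1).
    """
    a = profile.region_ratios(region_a)
    b = profile.region_ratios(region_b)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"need >= 2 defined positions per region, got {len(a)} and {len(b)}"
        )
    t, p = stats.ttest_ind(b, a, equal_var=True, alternative="greater")
    if np.isnan(t):  # zero pooled variance
        if np.mean(b) == np.mean(a):
            return 0.0, 0.5
        return (np.inf, 0.0) if np.mean(b) > np.mean(a) else (-np.inf, 1.0)
    return float(t), float(p)


def _site_seed_length(site: TargetSite) -> int:
    return 8 if site.seed_match_type == "8mer" else 7


def top_expressed(expression: dict[str, float], k: int) -> set[str]:
    """Ids of the k most highly expressed miRNAs (ties broken by id)."""
    ranked = sorted(expression.items(), key=lambda kv: (-kv[1], kv[0]))
    return {m for m, _ in ranked[:k]}


def stratified_tests(
    sites: Sequence[TargetSite],
    clusters: dict[str, ReadCluster],
    utrs: dict[str, UtrReference],
    strata: Sequence[StratumLabel] = DEFAULT_STRATA,
    top_mirnas: Optional[set[str]] = None,
    P: int = 14,
) -> pd.DataFrame:
    """Per-stratum region t-tests, one row per stratum.

    Sites are restricted by their UTR's conservation flag (an unset flag
    matches only the full {C, N} stratum), by seed length (7 covers 7mer-A1
    and 7mer-m8; 8 covers 8mer) and, when ``top_mirnas`` is given, to sites
    of those miRNAs.  Strata with too little data yield NA statistics.
    """
    rows = []
    for stratum in strata:
        selected = []
        for site in sites:
            if _site_seed_length(site) not in stratum.seed_lengths:
                continue
            conserved = utrs[site.utr_id].conserved
            if stratum.conservation != frozenset({"C", "N"}):
                if conserved is None:
                    continue
                flag = "C" if conserved else "N"
                if flag not in stratum.conservation:
                    continue
            if top_mirnas is not None and site.mirna_id not in top_mirnas:
                continue
            selected.append(site)
        t = p = float("nan")
        if selected:
            profile = site_conversion_profile(selected, clusters, utrs, P=P)
            try:
                t, p = region_ttest(profile)
            except InsufficientDataError:
                pass
        rows.append({"stratum": str(stratum), "n_sites": len(selected), "t": t, "p": p})
    return pd.DataFrame(rows, columns=["stratum", "n_sites", "t", "p"])
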