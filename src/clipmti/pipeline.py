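"""End-to-end orchestration: preprocess -> (reversion) -> align -> cluster
-> target identification -> conversion statistics.

``run_pipeline`` wires the stage modules together, tracks read counts in
raw-read units so the summary conserves every input read
(input = discarded_adapter + discarded_quality + unmapped + mapped), and
writes plain-TSV outputs: the ranked site report, cluster BED, per-position
conversion profile, stratified test table, per-cluster conversion counts
(so statistics can be recomputed without re-aligning) and a run summary.

Outputs are deterministic: mapping may be spread over worker processes but
results are merged in input order, so worker count never changes a byte.
"""

from __future__ import annotations

import concurrent.futures
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io_formats
from .aligner import MappedRead, build_index
from .clustering import ClusterParams, ReadCluster, build_clusters, filter_clusters, write_cluster_bed
from .conversion_stats import (
    DEFAULT_STRATA,
    InsufficientDataError,
    region_ttest,
    site_conversion_profile,
    stratified_tests,
    top_expressed,
)
from .io_formats import SequencedRead
from .preprocess import PreprocessParams, preprocess_reads
from .reversion import map_read
from .target_id import TargetSite, find_seed_matches, rank_mtis

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "recompute_stats"]


@dataclass
class PipelineConfig:
    """All tunables for a run; ``mode`` gates the PAR-CLIP-specific steps.

    In CLIP mode the C->T reversion expansion is skipped and the cluster
    conversion-fraction filter is inactive (no conversions are called).
    """

    mode: str = "parclip"
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    max_mismatch: int = 1
    seed_k: int = 10
    flank: int = 0
    profile_positions: int = 14
    top_k: int = 102
    phred_offset: int = 33
    workers: int = 1

    def __post_init__(self) -> None:
        if self.mode not in ("clip", "parclip"):
            raise ValueError("mode must be 'clip' or 'parclip'")
        if self.workers < 1:
            raise ValueError("workers must be >= 1")

    @property
    def parclip(self) -> bool:
        return self.mode == "parclip"


@dataclass
class PipelineResult:
    summary: dict
    mapped: list[MappedRead]
    clusters: list[ReadCluster]
    sites: list[TargetSite]
    profile: object
    strata: pd.DataFrame


_WORKER_STATE: tuple = ()


def _init_worker(index, max_mismatch, parclip) -> None:
    global _WORKER_STATE
    _WORKER_STATE = (index, max_mismatch, parclip)


def _map_one(read: SequencedRead) -> Optional[MappedRead]:
    index, max_mismatch, parclip = _WORKER_STATE
    return map_read(read, index, max_mismatch, parclip)


def _map_all(reads, index, config: PipelineConfig) -> list[Optional[MappedRead]]:
    if config.workers == 1:
        return [map_read(r, index, config.max_mismatch, config.parclip) for r in reads]
    with concurrent.futures.ProcessPoolExecutor(
        max_workers=config.workers,
        initializer=_init_worker,
        initargs=(index, config.max_mismatch, config.parclip),
    ) as pool:
        # executor.map preserves input order, so the merge is deterministic
        return list(pool.map(_map_one, reads, chunksize=64))


def run_pipeline(
    config: PipelineConfig,
    reads_path,
    utrs_path,
    mirnas_path,
    out_dir,
    expression_path=None,
    validated_path=None,
    conservation_path=None,
) -> PipelineResult:
    """Run every stage on FASTQ reads against a 3'UTR FASTA reference.

    Writes sites.tsv, clusters.bed, profile.tsv, strata.tsv,
    conversion_counts.tsv and summary.tsv under ``out_dir``; partial outputs
    are removed if a stage fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(config, reads_path, utrs_path, mirnas_path, out_dir,
                    expression_path, validated_path, conservation_path, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _stage(name: str):
    logger.info("stage: %s", name)


def _run(config, reads_path, utrs_path, mirnas_path, out_dir,
         expression_path, validated_path, conservation_path, written) -> PipelineResult:
    conservation = io_formats.load_conservation(conservation_path) if conservation_path else {}
    expression = io_formats.load_expression(expression_path) if expression_path else {}
    validated = io_formats.load_validated(validated_path) if validated_path else set()

    try:
        utrs = io_formats.load_utrs(utrs_path, conservation)
        mirnas = io_formats.load_mirnas(mirnas_path, expression)
    except Exception as exc:
        raise RuntimeError(f"reference loading failed: {exc}") from exc

    _stage("preprocess")
    try:
        raw = io_formats.read_fastq(reads_path, config.phred_offset)
        collapsed, counts = preprocess_reads(raw, config.preprocess)
    except Exception as exc:
        raise RuntimeError(f"preprocess stage failed: {exc}") from exc

    _stage("align")
    try:
        index = build_index(utrs, k=config.seed_k)
        mapped_or_none = _map_all(collapsed, index, config)
    except Exception as exc:
        raise RuntimeError(f"alignment stage failed: {exc}") from exc
    mapped = [m for m in mapped_or_none if m is not None]
    n_mapped = sum(m.multiplicity for m in mapped)
    counts["mapped"] = n_mapped
    counts["unmapped"] = counts["surviving"] - n_mapped

    _stage("cluster")
    try:
        clusters_all = build_clusters(mapped, utrs, config.cluster)
        clusters = filter_clusters(clusters_all, config.cluster, parclip_mode=config.parclip)
    except Exception as exc:
        raise RuntimeError(f"clustering stage failed: {exc}") from exc
    counts["clusters_prefilter"] = len(clusters_all)
    counts["clusters"] = len(clusters)

    _stage("target identification")
    try:
        utr_by_id = {u.utr_id: u for u in utrs}
        sites: list[TargetSite] = []
        for cluster in clusters:
            sites.extend(
                find_seed_matches(cluster, utr_by_id[cluster.utr_id], mirnas, config.flank)
            )
        sites = rank_mtis(sites, validated, expression)
    except Exception as exc:
        raise RuntimeError(f"target identification stage failed: {exc}") from exc
    counts["sites"] = len(sites)

    _stage("conversion statistics")
    cluster_by_id = {c.cluster_id: c for c in clusters}
    try:
        profile = site_conversion_profile(sites, cluster_by_id, utr_by_id, P=config.profile_positions)
        try:
            t, p = region_ttest(profile)
            counts["region_t"] = t
            counts["region_p"] = p
        except InsufficientDataError:
            counts["region_t"] = counts["region_p"] = float("nan")
        strata_frames = [
            stratified_tests(sites, cluster_by_id, utr_by_id, DEFAULT_STRATA,
                             P=config.profile_positions).assign(mirna_set="all")
        ]
        if expression:
            top = top_expressed(expression, config.top_k)
            strata_frames.append(
                stratified_tests(sites, cluster_by_id, utr_by_id, DEFAULT_STRATA,
                                 top_mirnas=top, P=config.profile_positions)
                .assign(mirna_set="top_expressed")
            )
        strata = pd.concat(strata_frames, ignore_index=True)
    except Exception as exc:
        raise RuntimeError(f"statistics stage failed: {exc}") from exc

    _stage("write outputs")
    paths = {name: out_dir / name for name in
             ["sites.tsv", "clusters.bed", "profile.tsv", "strata.tsv",
              "conversion_counts.tsv", "summary.tsv"]}
    written.extend(paths.values())
    io_formats.write_site_report(sites, paths["sites.tsv"])
    write_cluster_bed(clusters, paths["clusters.bed"])
    profile.to_frame().to_csv(paths["profile.tsv"], sep="\t", index=False)
    strata.to_csv(paths["strata.tsv"], sep="\t", index=False)
    _write_conversion_counts(clusters, paths["conversion_counts.tsv"])
    with open(paths["summary.tsv"], "w") as out:
        for key, value in counts.items():
            out.write(f"{key}\t{value}\n")
            logger.info("summary: %s = %s", key, value)

    return PipelineResult(summary=counts, mapped=mapped, clusters=clusters,
                          sites=sites, profile=profile, strata=strata)


def _write_conversion_counts(clusters, path) -> None:
    with open(path, "w") as out:
        out.write("cluster_id\tutr_id\tutr_pos\tconverted\tcovering\n")
        for c in clusters:
            for pos in sorted(c.per_base_conversion):
                conv, cov = c.per_base_conversion[pos]
                out.write(f"{c.cluster_id}\t{c.utr_id}\t{pos}\t{conv}\t{cov}\n")


def recompute_stats(
    sites_path,
    counts_path,
    utrs_path,
    conservation_path=None,
    expression_path=None,
    top_k: int = 102,
    P: int = 14,
):
    """Rebuild profile and stratified tests from saved pipeline intermediates.

    Uses the site report plus the per-cluster conversion-count table, so no
    re-alignment is needed.  Returns (profile, strata DataFrame).
    """
    conservation = io_formats.load_conservation(conservation_path) if conservation_path else {}
    expression = io_formats.load_expression(expression_path) if expression_path else {}
    utrs = io_formats.load_utrs(utrs_path, conservation)
    utr_by_id = {u.utr_id: u for u in utrs}

    sites_df = pd.read_csv(sites_path, sep="\t")
    counts_df = pd.read_csv(counts_path, sep="\t")

    clusters: dict[str, ReadCluster] = {}
    for cluster_id, group in counts_df.groupby("cluster_id"):
        per_base = {
            int(row.utr_pos): (int(row.converted), int(row.covering))
            for row in group.itertuples()
        }
        clusters[cluster_id] = ReadCluster(
            cluster_id=cluster_id,
            utr_id=str(group["utr_id"].iloc[0]),
            span_start=int(group["utr_pos"].min()),
            span_end=int(group["utr_pos"].max()) + 1,
            members=[],
            read_support=0,
            conversion_read_fraction=0.0,
            per_base_conversion=per_base,
        )

    sites = []
    for row in sites_df.itertuples():
        site = TargetSite(
            utr_id=str(row.utr_id),
            cluster_id=str(row.cluster_id),
            site_start=int(row.site_start) - 1,  # report is 1-based inclusive
            site_end=int(row.site_end),
            mirna_id=str(row.mirna_id),
            seed_match_type=str(row.seed_match_type),
            read_support=int(row.read_support),
        )
        # a site may reference a cluster with no T positions at all
        clusters.setdefault(
            site.cluster_id,
            ReadCluster(site.cluster_id, site.utr_id, site.site_start, site.site_end,
                        [], 0, 0.0, {}),
        )
        sites.append(site)

    profile = site_conversion_profile(sites, clusters, utr_by_id, P=P)
    frames = [
        stratified_tests(sites, clusters, utr_by_id, DEFAULT_STRATA, P=P).assign(mirna_set="all")
    ]
    if expression:
        frames.append(
            stratified_tests(sites, clusters, utr_by_id, DEFAULT_STRATA,
                             top_mirnas=top_expressed(expression, top_k), P=P)
            .assign(mirna_set="top_expressed")
        )
    return profile, pd.concat(frames, ignore_index=True)
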