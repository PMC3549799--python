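"""Synthetic PAR-CLIP data with known ground truth.

The generator emulates what an Argonaute PAR-CLIP library looks like after
sequencing: random 3'UTRs carrying implanted seed-complementary target
sites, reads piled over each site, position-dependent T->C conversion
(high in the region pairing miRNA positions 8-14, low over the seed-paired
positions 1-7, near-background elsewhere), uniform sequencing error, 3'
adapter read-through, decaying quality strings, and uniformly scattered
background reads.  Every implanted site and injected conversion is recorded
in a truth table so pipeline recovery can be scored exactly.

The conversion model is a per-T independent Bernoulli with region-dependent
rate — the simplest model under which the positional 8-14 vs 1-7 contrast
is literally true.  ``simulate_profile`` draws pooled per-position counts
from the same model directly, for statistical calibration experiments that
do not need reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from ._dna import revcomp
from .conversion_stats import ConversionProfile
from .io_formats import MatureMirna, SequencedRead, UtrReference, write_fastq

__all__ = [
    "SimulationConfig",
    "TruthSite",
    "TruthRead",
    "TruthTable",
    "simulate_references",
    "simulate_reads",
    "simulate_dataset",
    "write_simulation",
    "simulate_profile",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic PAR-CLIP library.

    Defaults describe a desk-scale experiment: 30 UTRs of 400-800 nt, 8
    miRNAs, 2 implanted sites per UTR with 8-20 reads each, and conversion
    probabilities of 0.40 per covered T in the effector region (positions
    8-14) versus 0.05 in the seed-paired region (1-7) and 0.02 elsewhere.
    """

    seed: int = 0
    n_utrs: int = 30
    utr_length_range: tuple[int, int] = (400, 800)
    gc_fraction: float = 0.5
    n_mirnas: int = 8
    mirna_length: int = 22
    n_sites_per_utr: int = 2
    site_type_mix: dict = field(
        default_factory=lambda: {"8mer": 0.4, "7mer-m8": 0.3, "7mer-A1": 0.3}
    )
    conserved_fraction: float = 0.5
    validated_fraction: float = 0.2
    reads_per_site_range: tuple[int, int] = (8, 20)
    background_read_count: int = 200
    read_length_range: tuple[int, int] = (20, 36)
    conv_prob_seed_region: float = 0.05
    conv_prob_effector_region: float = 0.40
    background_conversion: float = 0.02
    seq_error_rate: float = 0.001
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    adapter_readthrough_fraction: float = 0.3
    qual_start: int = 38
    qual_end: int = 26
    low_qual_tail_prob: float = 0.25
    low_qual_tail_max: int = 3
    site_margin: int = 20
    site_spacing: int = 60
    min_effector_t: int = 2

    def __post_init__(self) -> None:
        for name in (
            "gc_fraction",
            "conserved_fraction",
            "validated_fraction",
            "conv_prob_seed_region",
            "conv_prob_effector_region",
            "background_conversion",
            "seq_error_rate",
            "adapter_readthrough_fraction",
            "low_qual_tail_prob",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for name in ("utr_length_range", "reads_per_site_range", "read_length_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 1:
                raise ValueError(f"{name} must be a non-empty positive range")


@dataclass(frozen=True)
class TruthSite:
    utr_id: str
    site_start: int  # 0-based half-open, matching TargetSite coordinates
    site_end: int
    mirna_id: str
    seed_match_type: str
    conserved: bool
    validated: bool

    @property
    def anchor(self) -> int:
        """UTR coordinate pairing miRNA position 1."""
        return self.site_end if self.seed_match_type == "7mer-m8" else self.site_end - 1


@dataclass(frozen=True)
class TruthRead:
    read_id: str
    utr_id: str
    start: int
    end: int
    site_index: Optional[int]  # index into TruthTable.sites; None = background
    conversions: tuple[int, ...]  # UTR coordinates of injected T->C events


@dataclass
class TruthTable:
    sites: list[TruthSite] = field(default_factory=list)
    reads: list[TruthRead] = field(default_factory=list)


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(_BASES, size=length, p=p)


def simulate_references(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> tuple[list[UtrReference], list[MatureMirna], TruthTable]:
    """Generate UTRs with implanted target sites, miRNAs and the truth table.

    Sites are implanted by writing the exact reverse complement of the
    miRNA seed (plus the position-1 A where the type demands it) into the
    UTR at non-overlapping, well-separated positions; the base neighbouring
    a 7mer site is forced so the implanted type is unambiguous.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng

    mirnas: list[MatureMirna] = []
    seeds_seen: set[str] = set()
    expr = np.sort(rng.lognormal(mean=3.0, sigma=1.0, size=config.n_mirnas))[::-1]
    for i in range(config.n_mirnas):
        while True:
            seq = "".join(rng.choice(_BASES, size=config.mirna_length))
            if seq[1:8] not in seeds_seen:
                seeds_seen.add(seq[1:8])
                break
        mirnas.append(MatureMirna(f"mir-{i + 1:03d}", seq, expression=float(expr[i])))

    usable = config.utr_length_range[0] - 2 * config.site_margin
    if config.n_sites_per_utr > 0 and usable < config.n_sites_per_utr * config.site_spacing:
        raise ValueError(
            "infeasible site packing: UTRs too short for "
            f"{config.n_sites_per_utr} sites spaced {config.site_spacing} nt apart"
        )

    type_names = list(config.site_type_mix)
    type_probs = np.array([config.site_type_mix[t] for t in type_names], dtype=float)
    type_probs = type_probs / type_probs.sum()

    utrs: list[UtrReference] = []
    truth = TruthTable()
    for u in range(config.n_utrs):
        utr_id = f"utr{u + 1:04d}"
        length = int(rng.integers(config.utr_length_range[0], config.utr_length_range[1] + 1))
        seq = _random_seq(rng, length, config.gc_fraction)
        conserved = bool(rng.random() < config.conserved_fraction)
        placed: list[int] = []
        for _ in range(config.n_sites_per_utr):
            mirna = mirnas[int(rng.integers(config.n_mirnas))]
            stype = type_names[int(rng.choice(len(type_names), p=type_probs))]
            seed7 = revcomp(mirna.sequence[1:8])
            if stype == "8mer":
                motif = seed7 + "A"
            elif stype == "7mer-m8":
                motif = seed7
            else:  # 7mer-A1
                motif = revcomp(mirna.sequence[1:7]) + "A"
            # anchor (position-1 coordinate) relative to the site start
            anchor_off = len(motif) if stype == "7mer-m8" else len(motif) - 1
            start = None
            for _attempt in range(500):
                cand = int(
                    rng.integers(config.site_margin, length - config.site_margin - 9 + 1)
                )
                if any(abs(cand - p) < config.site_spacing for p in placed):
                    continue
                # 4SU crosslinking needs uridines in the protein-contact
                # region: only implant where the effector window (positions
                # 8-14) will hold enough reference T's to be captured
                anchor = cand + anchor_off
                n_t = 0
                for coord in range(anchor - 13, anchor - 6):
                    if stype == "7mer-A1" and coord == cand - 1:
                        continue  # this base is forced after placement; don't count it
                    base = motif[coord - cand] if cand <= coord < cand + len(motif) else seq[coord]
                    if base == "T":
                        n_t += 1
                if n_t >= config.min_effector_t:
                    start = cand
                    break
            if start is None:
                raise ValueError(f"could not place site in {utr_id}; relax spacing or margin")
            placed.append(start)
            if stype == "7mer-m8":
                seq[start + 7] = rng.choice([b for b in "CGT"])  # position-1 base != A
            elif stype == "7mer-A1":
                # force the 5'-adjacent base so the match cannot extend to m8
                seq[start - 1] = rng.choice([b for b in "ACGT" if b != seed7[0]])
            seq[start : start + len(motif)] = list(motif)
            validated = bool(rng.random() < config.validated_fraction)
            truth.sites.append(
                TruthSite(utr_id, start, start + len(motif), mirna.mirna_id, stype, conserved, validated)
            )
        utrs.append(UtrReference(utr_id, "".join(seq), conserved=conserved))
    return utrs, mirnas, truth


def _emit_read(
    rng: np.random.Generator,
    config: SimulationConfig,
    read_id: str,
    utr: UtrReference,
    start: int,
    length: int,
    site: Optional[TruthSite],
) -> tuple[SequencedRead, TruthRead]:
    seq = utr.sequence
    bases = list(seq[start : start + length])
    if site is not None:
        anchor = site.anchor
        effector = range(anchor - 13, anchor - 6)  # positions 8-14
        seed_region = range(anchor - 6, anchor + 1)  # positions 1-7
    conversions: list[int] = []
    for i, b in enumerate(bases):
        if b != "T":
            continue
        pos = start + i
        rate = config.background_conversion
        if site is not None:
            if pos in effector:
                rate = config.conv_prob_effector_region
            elif pos in seed_region:
                rate = config.conv_prob_seed_region
        if rng.random() < rate:
            bases[i] = "C"
            conversions.append(pos)
    # uniform sequencing error after conversion injection
    for i in range(len(bases)):
        if rng.random() < config.seq_error_rate:
            bases[i] = rng.choice([b for b in "ACGT" if b != bases[i]])
    if rng.random() < config.adapter_readthrough_fraction:
        bases.extend(config.adapter)
    n = len(bases)
    if n > 1:
        quals = [
            int(round(config.qual_start + (config.qual_end - config.qual_start) * i / (n - 1)))
            for i in range(n)
        ]
    else:
        quals = [config.qual_start]
    if config.low_qual_tail_max > 0 and rng.random() < config.low_qual_tail_prob:
        tail = int(rng.integers(1, config.low_qual_tail_max + 1))
        for i in range(n - tail, n):
            quals[i] = int(rng.integers(2, 16))
    read = SequencedRead(read_id, "".join(bases), tuple(quals))
    truth_read = TruthRead(read_id, utr.utr_id, start, start + length, None, tuple(conversions))
    return read, truth_read


def simulate_reads(
    config: SimulationConfig,
    utrs: list[UtrReference],
    truth: TruthTable,
    rng: Optional[np.random.Generator] = None,
) -> list[SequencedRead]:
    """Draw site-covering and background reads; truth.reads is filled in.

    Site reads have jittered starts constrained to cover the full site;
    background reads start uniformly on a uniformly chosen UTR.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    utr_by_id = {u.utr_id: u for u in utrs}
    reads: list[SequencedRead] = []
    for si, site in enumerate(truth.sites):
        utr = utr_by_id[site.utr_id]
        n_reads = int(rng.integers(config.reads_per_site_range[0], config.reads_per_site_range[1] + 1))
        for j in range(n_reads):
            length = int(rng.integers(config.read_length_range[0], config.read_length_range[1] + 1))
            lo = max(0, site.site_end - length)
            hi = min(len(utr) - length, site.site_start)
            start = int(rng.integers(lo, hi + 1)) if lo <= hi else max(0, min(len(utr) - length, site.site_start))
            read, truth_read = _emit_read(
                rng, config, f"site{si:04d}_r{j:03d}", utr, start, length, site
            )
            reads.append(read)
            truth.reads.append(replace(truth_read, site_index=si))
    for j in range(config.background_read_count):
        utr = utrs[int(rng.integers(len(utrs)))]
        length = int(rng.integers(config.read_length_range[0], config.read_length_range[1] + 1))
        length = min(length, len(utr))
        start = int(rng.integers(0, len(utr) - length + 1))
        read, truth_read = _emit_read(rng, config, f"bg_r{j:05d}", utr, start, length, None)
        reads.append(read)
        truth.reads.append(truth_read)
    return reads


def simulate_dataset(
    config: SimulationConfig,
) -> tuple[list[UtrReference], list[MatureMirna], TruthTable, list[SequencedRead]]:
    """References plus reads from one seeded generator (fully reproducible)."""
    rng = np.random.default_rng(config.seed)
    utrs, mirnas, truth = simulate_references(config, rng)
    reads = simulate_reads(config, utrs, truth, rng)
    return utrs, mirnas, truth, reads


def _write_fasta(entries, path) -> None:
    with open(path, "w") as out:
        for name, seq in entries:
            out.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")


def write_simulation(config: SimulationConfig, out_dir) -> dict[str, Path]:
    """Generate a dataset and write every pipeline input plus truth TSVs.

    Emits reads.fastq, utrs.fasta, mirnas.fasta, conservation.tsv,
    expression.tsv, validated.tsv, truth_sites.tsv and truth_reads.tsv.
    The same config (including seed) always produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    utrs, mirnas, truth, reads = simulate_dataset(config)
    paths = {name: out_dir / fname for name, fname in [
        ("reads", "reads.fastq"),
        ("utrs", "utrs.fasta"),
        ("mirnas", "mirnas.fasta"),
        ("conservation", "conservation.tsv"),
        ("expression", "expression.tsv"),
        ("validated", "validated.tsv"),
        ("truth_sites", "truth_sites.tsv"),
        ("truth_reads", "truth_reads.tsv"),
    ]}
    write_fastq(reads, paths["reads"])
    _write_fasta([(u.utr_id, u.sequence) for u in utrs], paths["utrs"])
    _write_fasta([(m.mirna_id, m.sequence) for m in mirnas], paths["mirnas"])
    with open(paths["conservation"], "w") as out:
        for u in utrs:
            out.write(f"{u.utr_id}\t{int(bool(u.conserved))}\n")
    with open(paths["expression"], "w") as out:
        for m in mirnas:
            out.write(f"{m.mirna_id}\t{m.expression:.4f}\n")
    with open(paths["validated"], "w") as out:
        for s in truth.sites:
            if s.validated:
                out.write(f"{s.mirna_id}\t{s.utr_id}\n")
    with open(paths["truth_sites"], "w") as out:
        out.write("utr_id\tsite_start\tsite_end\tmirna_id\tseed_match_type\tconserved\tvalidated\n")
        for s in truth.sites:
            out.write(
                f"{s.utr_id}\t{s.site_start}\t{s.site_end}\t{s.mirna_id}\t"
                f"{s.seed_match_type}\t{int(s.conserved)}\t{int(s.validated)}\n"
            )
    with open(paths["truth_reads"], "w") as out:
        out.write("read_id\tutr_id\tstart\tend\tsite_index\tconversions\n")
        for r in truth.reads:
            site = "" if r.site_index is None else str(r.site_index)
            conv = ",".join(map(str, r.conversions))
            out.write(f"{r.read_id}\t{r.utr_id}\t{r.start}\t{r.end}\t{site}\t{conv}\n")
    return paths


def simulate_profile(
    rng: np.random.Generator,
    coverage: int = 200,
    rate_seed_region: float = 0.05,
    rate_effector_region: float = 0.40,
    P: int = 14,
) -> ConversionProfile:
    """Draw a pooled conversion profile directly from the Bernoulli model.

    Positions 1-7 convert at ``rate_seed_region`` and positions 8-14 at
    ``rate_effector_region``, each with ``coverage`` covering reads — the
    per-position counts the read-level simulation pools, without the reads.
    Intended for calibration experiments (type-I error, power) that need
    many replicates.
    """
    covering = np.full(P, coverage, dtype=np.int64)
    rates = np.array(
        [rate_seed_region if k <= 7 else rate_effector_region for k in range(1, P + 1)]
    )
    converted = rng.binomial(covering, rates)
    return ConversionProfile(converted, covering)
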