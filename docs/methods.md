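# Methods

## The problem and the approach

Argonaute CLIP-seq reads are sense-strand fragments of bound transcripts;
because miRNA targeting is mediated by seed complementarity in 3'UTRs, the
pipeline aligns reads exclusively to 3'UTR reference sequences rather than
the genome. PAR-CLIP adds a positional signal — T→C substitutions at
4SU-crosslinked uridines — at the price of reads that differ from their
true locus at several positions.

The central design choice is how to map such reads. Raising the aligner's
mismatch budget to two admits *all* substitution types and inflates both
search space and mis-mappings. Instead, each read with *c* cytidines is
expanded into 1 + *c* sequences (the original plus one single-C→T revert
per C) and every variant is aligned under the ordinary one-mismatch budget.
A read whose deviations are one conversion plus one further event (second
conversion or a sequencing error) still maps: the revert removes one
C-over-T difference and the mismatch allowance absorbs the other. Only the
C/T substitution type is privileged, which is exactly the biology of the
assay.

After alignment, all variant hits are reconciled onto the *original* read.
Every distinct candidate placement is re-scored against the original
bases; read-C-over-reference-T differences are recorded as conversion
events and only the remainder count as mismatches (so a conversion
absorbed by the mismatch allowance is still reported as signal).
Placements are chosen by fewest mismatches, then most conversions
(favouring the crosslink interpretation), then lexicographically smallest
(UTR id, offset) — fully deterministic. Reads tied across loci keep the
single tie-broken placement. In CLIP mode the expansion is skipped and no
conversions are called; every difference is a plain mismatch.

A read whose only deviations are k ≤ 2 conversions is therefore always
mappable, and a read with ≥ 3 conversions never is. This truncation is a
real property of the strategy and matters for interpretation (see
"Estimator bias" below).

## Alignment contract

Ungapped, substitution-only, forward-strand. The index stores every
length-k substring of every UTR (default k = 10; UTRs shorter than k are
skipped with a warning). Queries split the read into `max_mismatch + 1`
contiguous parts; by pigeonhole at least one part is mismatch-free, so
seeding each part's leading k-mer and verifying candidates by full Hamming
comparison is complete whenever every part is ≥ k long (reads ≥ 2k at the
default settings). Shorter reads fall back to an exhaustive scan of every
offset, so completeness holds at all read lengths; the tests assert exact
agreement with a brute-force Hamming oracle on random instances.

## Preprocessing rules

* 3' adapter: cut at the leftmost position where the adapter prefix
  matches the read suffix with overlap ≥ 5 and mismatch rate ≤ 0.1 (both
  exposed); trimmed reads shorter than 15 nt or containing N are discarded.
* Quality: 3' bases are stripped while the terminal phred is < 20
  (a strip-while rule, not sum trimming), then the 15-nt floor re-applies.
  Phred offset defaults to 33, with 64 selectable.
* Collapsing keys on the base string only; the representative keeps the
  first-seen id and qualities, and the multiplicity carries raw-read
  counts through clustering so compression never changes the biology.

## Clustering and filtering

Clusters are single-linkage components of the interval-overlap graph on
each UTR (overlap ≥ `min_overlap`, default 1 nt — the weakest consistent
reading of "minimum overlap", configurable upward). Filters: read support
(Σ multiplicities) ≥ 5; in PAR-CLIP mode additionally ≥ 20% of reads
(multiplicity-weighted) carrying ≥ 1 conversion. Collapsed multiplicities
count toward both thresholds.

## Seed matching and ranking

Site types follow the canonical definitions, strict Watson–Crick, G:U
wobble disallowed: 8mer (match to miRNA 2–8 + A opposite position 1),
7mer-m8 (match 2–8, no A), 7mer-A1 (match 2–7 + A, not extending to m8).
Types are exclusive and maximal. The scan window is the cluster span plus
a `flank` (default 0; crosslink sites sit near seeds, so a flank can be
useful on sparse data). TargetScan-style context scores are out of scope;
ranking uses the evidence hierarchy validated > expression (missing = −∞)
> seed strength > read support, with positional tie-breaks so ranks are a
deterministic permutation.

## Conversion statistics

Site position k is the UTR base pairing miRNA position k: the position-1
anchor is the A of an 8mer/7mer-A1 site, or the base 3'-adjacent to a
7mer-m8 site (whose span covers positions 2–8 only); positions increase
toward the mRNA 5' side, so positions 8–14 sit opposite the miRNA segment
just 3' of the seed. Per position, conversion counts are pooled over
sites from each site's cluster; positions whose UTR base is not T are
undefined (NaN) and excluded, never imputed.

The regional comparison is a two-sample equal-variance Student's t-test on
the per-position pooled ratios (up to 7 values per region), one-tailed for
effector (8–14) > seed-paired (1–7). The per-position unit was chosen over
per-site rates because the profile is the natural pooled summary and 7+7
observations match a small-sample t-test; it is the documented convention,
not the only defensible one. Degenerate inputs follow the limit
convention: zero pooled variance with equal means gives (t = 0, p = 0.5),
with unequal means (±∞, p = 0 or 1); fewer than two defined positions in a
region raises an explicit insufficient-data error rather than returning
NaN. Stratification restricts sites by their UTR's conservation flag
(C/N; an unset flag only matches the full {C,N} stratum), seed length
(7 = both 7mer types, 8 = 8mer) and optionally the top-k expressed miRNAs
(default k = 102); empty strata yield NA rows.

## The synthetic-data generator

The generator emulates a desk-scale PAR-CLIP experiment with defaults:
30 UTRs of 400–800 nt at GC 0.5; 8 miRNAs of 22 nt with distinct seeds;
2 implanted sites per UTR (mix 0.4/0.3/0.3 over 8mer/7mer-m8/7mer-A1),
site starts ≥ 60 nt apart and ≥ 20 nt from UTR ends; 8–20 reads per site
(20–36 nt) jittered to cover the site; 200 background reads uniform over
UTRs; per-T Bernoulli conversion at 0.40 in the effector window, 0.05 in
the seed-paired window, 0.02 elsewhere; sequencing error 0.001 per base;
30% adapter read-through; qualities decaying 38 → 26 with occasional
sub-20 tails; conservation flags at 0.5 and 20% of implanted interactions
marked validated; miRNA expression log-normal(3, 1).

Sites are implanted by writing the exact seed complement (plus the
position-1 A where the type demands it); the base neighbouring a 7mer
site is forced so the implanted type is unambiguous. Sites are only
placed where the effector window will hold ≥ 2 reference T's: 4SU
crosslinking requires uridines in the protein-contact region, so sites
without them cannot be captured by the assay and would be unobservable by
construction. Every implanted site and every injected conversion is
recorded in a truth table (conversions before sequencing error), and the
same seed always reproduces byte-identical output files.

The conversion model is deliberately the simplest one consistent with the
positional contrast: independent per-T Bernoulli with region-dependent
rates, no per-read crosslink-count structure, no RNA secondary structure,
no PCR-duplicate family structure beyond what collapsing needs, and no
splicing. Passing tests therefore demonstrate correctness of the
machinery under this model, not performance on the full complexity of
real libraries. `simulate_profile` draws pooled per-position counts from
the same model directly (coverage 200 per position, matching what the
end-to-end defaults pool) for calibration experiments that need many
replicates: type-I error of the region test is measured over 1000 null
replicates and power over 200 replicates at the default effect.

## Estimator bias of the conversion ratio

Because reads with ≥ 3 conversion events cannot map, the conversion ratio
among mapped reads is a downward-biased estimator of the generative
per-T conversion probability when that probability is high: at the
default 0.40 effector rate roughly 4–5% of site reads are lost, and they
carry about three times the average number of conversions, so pooled
effector ratios come out near 0.31–0.37 rather than 0.40 (background-read
and chance-site dilution contribute a further percent or two). The
positional *contrast* — the quantity the statistics test — is unaffected
in direction and remains overwhelming at these settings. Analyses that
need absolute conversion rates should model the truncation or lower the
mismatch-free conversion load per read.

## Determinism and parallelism

Every stage is deterministic: fixed tie-breaks in reconciliation, sorted
cluster construction with sequential ids, stable ranking sorts. Mapping
may be distributed over worker processes, but chunks are merged in input
order, so outputs are byte-identical for any worker count — verified in
the tests by comparing all report files across runs and worker counts.

## Problem sizes used in tests

The test suite and acceptance script run on the generator's default scale
(≈ 1000 reads, ≈ 18 kb of reference) plus 200-instance aligner-oracle
comparisons and 1000/200-replicate statistical calibrations; these sizes
give stable pass/fail behaviour at desk scale while keeping the whole
suite in the order of seconds.

## Known limitations

* Single-end reads only; no 5' adapter handling.
* Forward-strand, ungapped alignment with substitutions only.
* Multi-mapping reads keep one deterministic placement; there is no
  multi-map reporting mode.
* 6mer and offset-6mer site types, wobble seeds and compensatory 3'
  pairing are not considered; context-score features are not computed.
* Absolute conversion-rate estimates are truncation-biased (above).
* The stratified tests condition on per-UTR (not per-site) conservation
  flags.
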