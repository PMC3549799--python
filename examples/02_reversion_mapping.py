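"""The C->T reversion trick that makes conversion-bearing reads mappable.

PAR-CLIP leaves T->C substitutions at crosslink positions, so a read can
differ from its true locus at several positions and fail strict alignment.
Expanding each read into single-C->T revert variants and aligning all of
them restores mappability, and reconciliation reports the conversions.
"""

from clipmti.aligner import build_index
from clipmti.io_formats import SequencedRead, UtrReference
from clipmti.reversion import expand_c_to_t, map_read

read = SequencedRead("example", "AATGCTCAATGGCGA", tuple([35] * 15))
print(f"read:     {read.bases}")
print("expansion (original first, then one variant per C):")
for v in expand_c_to_t(read):
    label = "original" if v.reverted_position is None else f"revert C at {v.reverted_position}"
    print(f"  {v.variant_bases}   ({label})")

# a reference locus where the read's two C's sit over reference T's:
# the original read has 2 mismatches and cannot map within the 1-mismatch
# allowance, but one reverted variant aligns and rescues it
site = "AATGTTTAATGGCGA"  # reference: T where the read shows its first two C's
utr = UtrReference("utr1", "GATTAGGATTAG" + site + "GATTAGGATTAG")
mapped = map_read(read, build_index([utr], k=8), max_mismatch=1, parclip=True)
print(f"\nmapped at {mapped.utr_id}:{mapped.start}-{mapped.end}")
print(f"conversion positions (read C over reference T): {sorted(mapped.conversion_positions)}")
print(f"residual mismatches: {sorted(mapped.mismatch_positions)}")
print(
    "\nThe conversion offsets are the crosslink signature: counted as signal,\n"
    "not as alignment error, even when the mismatch allowance absorbed them."
)
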