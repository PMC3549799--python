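"""Small DNA-string helpers shared across the package.

All sequences are stored internally as uppercase DNA over {A,C,G,T,N};
miRNA inputs given as RNA (U) are normalised on read.
"""

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an uppercase DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def normalize(seq: str) -> str:
    """Uppercase and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")
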