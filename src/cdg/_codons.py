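"""Codon alphabet constants shared across modules."""

from itertools import product

#: All 64 codons in lexicographic order (AAA ... TTT); the feature-vector index.
CODONS = ["".join(p) for p in product("ACGT", repeat=3)]

#: Stop codons of the standard genetic code.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: The 61 sense codons, lexicographic.
SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]
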