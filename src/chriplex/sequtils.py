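"""Small nucleotide-sequence helpers shared across modules."""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")

VALID_BASES = frozenset("ACGT")


def complement(base: str) -> str:
    """Watson-Crick complement of a single base (U treated as A's partner)."""
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA/RNA sequence (case-preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


def normalize_rna(seq: str) -> str:
    """Uppercase and map U to T so RNA and DNA share one alphabet."""
    return seq.upper().replace("U", "T")


def max_run_in_alphabet(seq: str, alphabet: frozenset[str] | set[str]) -> int:
    """Length of the longest run of characters drawn from *alphabet*."""
    best = cur = 0
    for ch in seq:
        if ch in alphabet:
            cur += 1
            if cur > best:
                best = cur
        else:
            cur = 0
    return best
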