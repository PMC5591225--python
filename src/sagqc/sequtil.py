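"""Small sequence helpers shared across modules."""
from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def gc_fraction(seq: str) -> float:
    """G+C over A+C+G+T (N excluded from the denominator).

    Returns 0.0 for a sequence with no unambiguous bases.
    """
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt
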