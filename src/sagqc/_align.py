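"""Thin wrappers around edlib used by the internal toy aligner and the
16S screen. Edit-distance based, so identities are exact for
substitution-only divergence and slightly conservative under indels."""
from __future__ import annotations

import edlib

from .sequtil import revcomp


def global_identity(a: str, b: str) -> float:
    """Global (NW) identity in [0,1]: 1 - editdist / max(len)."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="distance")
    return 1.0 - res["editDistance"] / max(len(a), len(b))


def best_infix_hit(query: str, target: str, max_divergence: float = 0.35):
    """Best infix (HW) placement of query within target.

    Returns (t_start, t_end, identity_fraction) or None when no placement
    within the divergence budget exists.
    """
    if not query or not target:
        return None
    k = max(1, int(max_divergence * len(query)))
    res = edlib.align(query, target, mode="HW", task="locations", k=k)
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s, e = res["locations"][0]
    e += 1  # edlib end is inclusive
    span = e - s
    identity = 1.0 - res["editDistance"] / max(len(query), span)
    return int(s), int(e), identity


def best_infix_hit_stranded(query: str, target: str, max_divergence: float = 0.35):
    """Best of forward/reverse-complement infix placements.

    Returns (t_start, t_end, identity_fraction, strand) or None.
    """
    fwd = best_infix_hit(query, target, max_divergence)
    rev = best_infix_hit(revcomp(query), target, max_divergence)
    if fwd is None and rev is None:
        return None
    if rev is None or (fwd is not None and fwd[2] >= rev[2]):
        return (*fwd, "+")
    return (*rev, "-")
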