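import numpy as np
import pytest

from sagqc.intervals import IntervalSet
from sagqc.simulate import SimConfig, simulate_reference


@pytest.fixture(scope="session")
def small_genome():
    """A 50 kb reference with 30 genes, shared across tests."""
    cfg = SimConfig(genome_length=50_000, n_genes=30, seed=11)
    genome, annotation = simulate_reference(cfg)
    return cfg, genome, annotation


def random_interval_set(rng, seq_ids=("s",), max_pos=500, n=10):
    triples = []
    for _ in range(n):
        sid = seq_ids[rng.integers(len(seq_ids))]
        s = int(rng.integers(0, max_pos - 1))
        e = int(rng.integers(s + 1, max_pos + 1))
        triples.append((sid, s, e))
    return IntervalSet.from_intervals(triples), triples


def membership(triples, seq_ids, max_pos):
    """Per-base boolean oracle for an interval collection."""
    out = {sid: np.zeros(max_pos, dtype=bool) for sid in seq_ids}
    for sid, s, e in triples:
        out[sid][s:e] = True
    return out


def iset_membership(iset, seq_ids, max_pos):
    out = {sid: np.zeros(max_pos, dtype=bool) for sid in seq_ids}
    for sid in iset.per_seq:
        for s, e in iset.per_seq[sid]:
            out[sid][s:e] = True
    return out
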