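"""Contamination screen: TNF profiles, clustering, verdicts, GC, 16S OTUs."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sagqc.contam import (
    CANONICAL_4MERS,
    Verdict,
    classify_scaffolds,
    cluster_tnf,
    gc_screen,
    rdna_screen,
    tnf_profile,
)
from sagqc.io import FileFormatError, SequenceSet
from sagqc.sequtil import revcomp
from sagqc.simulate import SimConfig, random_sequence


def _naive_tnf(window_seq):
    """Brute-force sliding-window counter pooled with reverse complements."""
    counts = {k: 0 for k in CANONICAL_4MERS}
    for i in range(len(window_seq) - 3):
        k = window_seq[i:i + 4]
        if "N" in k or set(k) - set("ACGT"):
            continue
        counts[min(k, revcomp(k))] += 1
    total = sum(counts.values())
    return np.array([counts[k] / total for k in CANONICAL_4MERS])


class TestTnfProfile:
    def test_poly_a_two_windows(self):
        seqs = SequenceSet({"s": "A" * 12_000})
        m = tnf_profile(seqs, min_scaffold=10_000, window=5_000)
        assert m.rows == [("s", 0), ("s", 5_000)]
        col = CANONICAL_4MERS.index("AAAA")
        assert (m.values[:, col] == 1.0).all()

    def test_short_scaffold_contributes_no_rows(self):
        seqs = SequenceSet({"s": "A" * 9_999})
        assert tnf_profile(seqs).n_rows == 0

    def test_window_below_256_rejected(self):
        with pytest.raises(ValueError):
            tnf_profile(SequenceSet({"s": "A" * 20_000}), window=100)

    def test_rows_sum_to_one_and_match_naive_oracle(self):
        rng = np.random.default_rng(30)
        seq = random_sequence(rng, 10_000, 0.45)
        m = tnf_profile(SequenceSet({"s": seq}), min_scaffold=10_000, window=5_000)
        assert m.n_rows == 2
        np.testing.assert_allclose(m.values.sum(axis=1), 1.0, atol=1e-9)
        np.testing.assert_allclose(m.values[0], _naive_tnf(seq[:5_000]))

    def test_reverse_complement_invariance(self):
        rng = np.random.default_rng(31)
        seq = random_sequence(rng, 10_000, 0.5)
        m_fwd = tnf_profile(SequenceSet({"s": seq[:5_000]}), min_scaffold=5_000, window=5_000)
        m_rev = tnf_profile(
            SequenceSet({"s": revcomp(seq[:5_000])}), min_scaffold=5_000, window=5_000
        )
        np.testing.assert_allclose(m_fwd.values, m_rev.values, atol=1e-12)

    def test_high_n_windows_skipped(self):
        seq = "N" * 5_000 + "ACGT" * 1_250
        m = tnf_profile(SequenceSet({"s": seq}), min_scaffold=10_000, window=5_000)
        assert m.rows == [("s", 5_000)]


def _two_population_scaffolds(seed=32, n_each=5, length=50_000):
    rng = np.random.default_rng(seed)
    seqs = SequenceSet()
    origin = {}
    for i in range(n_each):
        sid = f"host_{i}"
        seqs.add(sid, random_sequence(rng, length, 0.54))
        origin[sid] = "host"
    for i in range(n_each):
        sid = f"bact_{i}"
        seqs.add(sid, random_sequence(rng, length, 0.30))
        origin[sid] = "contaminant"
    return seqs, origin


class TestClusterTnf:
    def test_two_gc_populations_recovered(self):
        seqs, origin = _two_population_scaffolds()
        m = tnf_profile(seqs)
        cl = cluster_tnf(m, seed=0)
        assert cl.k == 2
        # window-level accuracy >= 95 % under the best label permutation
        truth = np.array([origin[sid] == "host" for sid, _ in m.rows])
        pred = cl.window_labels == cl.window_labels[np.argmax(truth)]
        acc = max((pred == truth).mean(), (~pred == truth).mean())
        assert acc >= 0.95

    def test_homogeneous_input_single_cluster(self):
        rng = np.random.default_rng(33)
        seqs = SequenceSet(
            {f"s{i}": random_sequence(rng, 40_000, 0.5) for i in range(4)}
        )
        cl = cluster_tnf(tnf_profile(seqs), seed=0)
        assert cl.k == 1

    def test_determinism_under_seed(self):
        seqs, _ = _two_population_scaffolds(seed=34, n_each=3, length=30_000)
        m = tnf_profile(seqs)
        l1 = cluster_tnf(m, seed=5).window_labels
        l2 = cluster_tnf(m, seed=5).window_labels
        assert (l1 == l2).all()


class TestClassifyScaffolds:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["scaffold_id", "taxon", "e_value", "bit_score"])

    def test_host_hit(self):
        seqs = SequenceSet({"s1": "ACGT" * 100})
        v = classify_scaffolds(seqs, self._table([("s1", "host_species", 1e-30, 100.0)]),
                               host_rule="host_species")
        assert v["s1"] == Verdict("host", frozenset({"taxonomy"}))

    def test_contaminant_hit(self):
        seqs = SequenceSet({"s1": "ACGT" * 100})
        v = classify_scaffolds(seqs, self._table([("s1", "bacterium X", 1e-40, 90.0)]),
                               host_rule="host_species")
        assert v["s1"].label == "contaminant" and "taxonomy" in v["s1"].evidence

    def test_evalue_filter_with_tnf_fallback(self):
        """A scaffold whose only hit fails the e-value filter inherits the
        label of its (contaminant-anchored) TNF cluster."""
        seqs, origin = _two_population_scaffolds(seed=35, n_each=3, length=30_000)
        m = tnf_profile(seqs)
        cl = cluster_tnf(m, seed=0)
        table = self._table([
            ("host_0", "host_species", 1e-30, 200.0),
            ("bact_0", "bacterium Y", 1e-40, 150.0),
            ("bact_1", "bacterium Z", 1e-3, 50.0),  # fails the e-value filter
        ])
        v = classify_scaffolds(seqs, table, cl, host_rule="host_species")
        assert v["bact_1"] == Verdict("contaminant", frozenset({"tnf"}))
        assert v["host_1"] == Verdict("host", frozenset({"tnf"}))

    def test_no_hit_no_tnf_is_unknown(self):
        seqs = SequenceSet({"s1": "ACGT" * 100})
        v = classify_scaffolds(seqs, self._table([]), host_rule="host")
        assert v["s1"] == Verdict("unknown", frozenset())

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "tax.tsv"
        p.write_text("s1\tbacterium\tnot_a_number\n")
        with pytest.raises(FileFormatError, match=":1"):
            classify_scaffolds(SequenceSet({"s1": "ACGT"}), str(p))


class TestGcScreen:
    def test_all_gc_sequence(self):
        res = gc_screen(SequenceSet({"s": "GC" * 500}))
        assert res.gc_all == 1.0

    def test_pure_host_gc_unimodal(self):
        rng = np.random.default_rng(36)
        seqs = SequenceSet({f"s{i}": random_sequence(rng, 30_000, 0.54) for i in range(4)})
        res = gc_screen(seqs)
        assert res.gc_all == pytest.approx(0.54, abs=0.01)
        assert res.bimodal is False

    def test_mixture_bimodal_until_contaminants_removed(self):
        seqs, origin = _two_population_scaffolds(seed=37, n_each=4, length=40_000)
        before = gc_screen(seqs)
        assert before.bimodal is True
        verdicts = {sid: Verdict(origin[sid], frozenset({"taxonomy"})) for sid in seqs}
        after = gc_screen(seqs, verdicts)
        assert after.bimodal is False
        assert after.gc_host_only == pytest.approx(0.54, abs=0.01)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            gc_screen(SequenceSet())


class TestRdnaScreen:
    @pytest.fixture(scope="class")
    def query(self):
        rng = np.random.default_rng(38)
        return random_sequence(rng, 1_200, 0.5)

    def _embed(self, insert, seed, flank=2_000):
        rng = np.random.default_rng(seed)
        return random_sequence(rng, flank, 0.4) + insert + random_sequence(rng, flank, 0.4)

    def test_identical_copies_one_otu(self, query):
        seqs = SequenceSet({
            "s1": self._embed(query, 39),
            "s2": self._embed(query, 40),
        })
        table = rdna_screen(seqs, query)
        assert len(table) == 1 and len(table.otus[0].members) == 2

    def test_no_hits_empty_table(self, query):
        rng = np.random.default_rng(41)
        seqs = SequenceSet({"s1": random_sequence(rng, 4_000, 0.4)})
        assert len(rdna_screen(seqs, query)) == 0

    def test_diverged_variants_split_otus(self, query):
        """Two embedded 16S variants at ~90 % identity fall below the
        0.97 OTU threshold and found separate OTUs."""
        rng = np.random.default_rng(42)
        variant = list(query)
        for i in rng.choice(len(variant), size=int(0.10 * len(variant)), replace=False):
            variant[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[variant[i]]
        seqs = SequenceSet({
            "s1": self._embed(query, 43),
            "s2": self._embed("".join(variant), 44),
        })
        table = rdna_screen(seqs, query)
        assert len(table) == 2

    def test_minus_strand_hit_recovered(self, query):
        seqs = SequenceSet({"s1": self._embed(revcomp(query), 45)})
        table = rdna_screen(seqs, query)
        assert len(table) == 1
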