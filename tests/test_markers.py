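"""Six-frame translation and marker recovery against independent oracles."""
import numpy as np
import pytest
from Bio.Align import substitution_matrices
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq

from sagqc.io import SequenceSet
from sagqc.markers import (
    MarkerHit,
    MarkerSet,
    build_supermatrix,
    search_markers,
    self_score,
    six_frame_translate,
    translate_frame,
)
from sagqc.sequtil import revcomp

AA20 = "ARNDCQEGHILKMFPSTWYV"
_CODON_OF = {}
for codon, aa in standard_dna_table.forward_table.items():
    _CODON_OF.setdefault(aa, codon)


def reverse_translate(peptide):
    return "".join(_CODON_OF[a] for a in peptide)


def random_peptide(rng, n):
    return "".join(rng.choice(list(AA20), n))


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def sw_affine_oracle(a, b, gap_open=11.0, gap_extend=1.0):
    """Brute-force Gotoh local alignment score: BLOSUM62, first gap
    residue costs gap_open, each further residue gap_extend."""
    mat = substitution_matrices.load("BLOSUM62")
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = mat[a[i - 1], b[j - 1]]
            M[i][j] = max(0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s)
            Ix[i][j] = max(M[i - 1][j] - gap_open, Ix[i - 1][j] - gap_extend)
            Iy[i][j] = max(M[i][j - 1] - gap_open, Iy[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


class TestSixFrameTranslate:
    def test_standard_code(self):
        assert translate_frame("ATGAAA", 1) == "MK"

    def test_frame_offsets_drop_partial_codons(self):
        assert translate_frame("ATGAAA", 2) == "*"  # TGA-AA
        assert translate_frame("ATGAAA", 3) == "E"  # GAA-A

    def test_revcomp_swaps_frame_signs(self):
        rng = np.random.default_rng(80)
        seq = random_dna(rng, 300)
        fwd = six_frame_translate(seq)
        rev = six_frame_translate(revcomp(seq))
        for f in (1, 2, 3):
            assert rev[f] == fwd[-f]
            assert rev[-f] == fwd[f]

    def test_codons_with_n_become_x(self):
        assert translate_frame("ATGNAA", 1) == "MX"

    def test_short_sequence_empty_frames(self):
        assert all(v == "" for v in six_frame_translate("AC").values())

    def test_against_biopython_codon_oracle(self):
        rng = np.random.default_rng(81)
        seq = random_dna(rng, 300)
        for frame in (1, 2, 3, -1, -2, -3):
            s = seq if frame > 0 else revcomp(seq)
            off = abs(frame) - 1
            trimmed = s[off:off + 3 * ((len(s) - off) // 3)]
            expected = str(Seq(trimmed).translate())
            assert translate_frame(seq, frame) == expected


class TestSearchMarkers:
    @pytest.fixture(scope="class")
    def marker(self):
        rng = np.random.default_rng(82)
        pep = random_peptide(rng, 80)
        return pep, MarkerSet({"m1": [("taxA", pep)]})

    @pytest.mark.parametrize("offset", [0, 1, 2])
    def test_planted_marker_recovered_in_plus_and_minus_frames(self, marker, offset):
        """Plant the marker verbatim at each codon offset (and on the
        reverse strand): it is recovered with exactly its self-alignment
        score, which in turn matches the DP oracle."""
        pep, mset = marker
        rng = np.random.default_rng(83 + offset)
        insert = reverse_translate(pep)
        # left flank of 300+offset places the insert at codon offset `offset`
        scaffold = random_dna(rng, 300 + offset) + insert + random_dna(rng, 200)
        expected_self = self_score(pep)
        assert expected_self == sw_affine_oracle(pep, pep)

        (hit,) = search_markers(SequenceSet({"s": scaffold}), mset, min_score=60)
        assert hit.recovered and hit.frame == offset + 1
        assert hit.score == expected_self
        assert hit.aligned_columns == len(pep)

        # frame -k of the reverse complement reads the original forward strand
        (hit_rc,) = search_markers(SequenceSet({"s": revcomp(scaffold)}), mset, min_score=60)
        assert hit_rc.recovered and hit_rc.frame == -(offset + 1)
        assert hit_rc.score == expected_self

    def test_shuffled_scaffolds_not_recovered(self, marker):
        pep, mset = marker
        rng = np.random.default_rng(84)
        for _ in range(10):
            scaffold = random_dna(rng, 1_500)
            (hit,) = search_markers(SequenceSet({"s": scaffold}), mset, min_score=60)
            assert not hit.recovered

    def test_scores_match_dp_oracle_on_short_peptides(self):
        """Aligner scores equal the brute-force Gotoh oracle on random
        peptide pairs up to 50 residues."""
        from sagqc.markers import make_aligner

        rng = np.random.default_rng(85)
        aligner = make_aligner()
        for _ in range(15):
            a = random_peptide(rng, int(rng.integers(10, 50)))
            b = random_peptide(rng, int(rng.integers(10, 50)))
            assert float(aligner.score(a, b)) == sw_affine_oracle(a, b)

    def test_empty_marker_set_rejected(self):
        with pytest.raises(ValueError):
            search_markers(SequenceSet({"s": "ACGT" * 100}), MarkerSet({}))

    def test_recovery_increases_with_breadth(self):
        """More of the genome recovered -> at least as many markers found."""
        rng = np.random.default_rng(86)
        peps = [random_peptide(rng, 60) for _ in range(12)]
        mset = MarkerSet({f"m{i}": [("taxA", p)] for i, p in enumerate(peps)})
        # genome: markers planted at regular spacing
        pieces = []
        for p in peps:
            pieces.append(random_dna(rng, 400))
            pieces.append(reverse_translate(p))
        genome = "".join(pieces) + random_dna(rng, 400)
        counts = []
        for frac in (0.3, 0.6, 1.0):
            end = int(frac * len(genome))
            scaff = SequenceSet({"s": genome[:end]})
            hits = search_markers(scaff, mset, min_score=60)
            counts.append(sum(h.recovered for h in hits))
        assert counts == sorted(counts)
        assert counts[-1] == len(peps)


class TestSupermatrix:
    def test_hand_fixture_100_of_150(self):
        rng = np.random.default_rng(87)
        pep1 = random_peptide(rng, 100)
        pep2 = random_peptide(rng, 50)
        mset = MarkerSet({"m1": [("taxA", pep1)], "m2": [("taxA", pep2)]})
        hit1 = MarkerHit("m1", "s", 1, 500.0, 100, True,
                         rep_residues={i: pep1[i] for i in range(100)})
        hit2 = MarkerHit("m2", None, None, 0.0, 0, False)
        row = build_supermatrix([hit1, hit2], mset, "sag1")
        assert row.total_columns == 150
        assert row.ungapped_positions == 100
        assert row.recovery_pct == 50.0
        assert row.sequence == pep1 + "-" * 50

    def test_all_markers_recovered_fully(self):
        mset = MarkerSet({"m1": [("taxA", "MKL")]})
        hit = MarkerHit("m1", "s", 1, 99.0, 3, True, {0: "M", 1: "K", 2: "L"})
        row = build_supermatrix([hit], mset, "t")
        assert row.ungapped_positions == row.total_columns == 3

    def test_no_markers_recovered_all_gaps(self):
        mset = MarkerSet({"m1": [("taxA", "MKLV")]})
        row = build_supermatrix([], mset, "t")
        assert row.sequence == "----" and row.ungapped_positions == 0

    def test_gapped_reference_alignment_columns(self):
        """Representative residues land on their alignment columns, not
        on a compacted index."""
        mset = MarkerSet({"m1": [("taxA", "MK--LV"), ("taxB", "MKQPLV")]})
        hit = MarkerHit("m1", "s", 1, 99.0, 4, True, {0: "M", 1: "K", 2: "L", 3: "V"})
        row = build_supermatrix([hit], mset, "t")
        assert row.sequence == "MK--LV"
        assert row.ungapped_positions == 4

    def test_duplicate_hits_keep_best_score(self):
        mset = MarkerSet({"m1": [("taxA", "MKL")]})
        weak = MarkerHit("m1", "s", 1, 50.0, 1, True, {0: "M"})
        strong = MarkerHit("m1", "s", 2, 90.0, 3, True, {0: "M", 1: "K", 2: "L"})
        row = build_supermatrix([weak, strong], mset, "t")
        assert row.ungapped_positions == 3
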