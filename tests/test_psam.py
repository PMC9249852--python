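import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from parabind.psam import (PSAM, build_affinity_track, read_psam,
                           relative_affinity, scan_sequence, top_motifs,
                           windowed_max, write_psam)
from parabind.types import GenomeSequence

from conftest import naive_affinity, naive_revcomp, naive_track


class TestRelativeAffinity:
    def test_identity_model_scores_one(self, identity_psam):
        assert relative_affinity("AC", identity_psam) == 1.0

    def test_known_window_forward(self, two_base_psam):
        # brute-force enumeration of all 16 dinucleotides fixes these values
        assert relative_affinity("CT", two_base_psam) == pytest.approx(
            np.exp(-1), abs=1e-12)
        assert relative_affinity("AT", two_base_psam) == 1.0

    def test_enumeration_matches_oracle(self, two_base_psam):
        for w in map("".join, itertools.product("ACGT", repeat=2)):
            assert relative_affinity(w, two_base_psam) == pytest.approx(
                naive_affinity(w, two_base_psam), rel=1e-12)
        best = max(map("".join, itertools.product("ACGT", repeat=2)),
                   key=lambda w: naive_affinity(w, two_base_psam))
        assert best == "AT"

    def test_minus_strand_is_revcomp(self, two_base_psam):
        # revcomp("AG") == "CT"
        assert relative_affinity("AG", two_base_psam, "-") == pytest.approx(
            np.exp(-1), abs=1e-12)

    def test_window_with_n_scores_zero(self, two_base_psam):
        assert relative_affinity("AN", two_base_psam) == 0.0

    def test_wrong_length_raises(self, two_base_psam):
        with pytest.raises(ValueError):
            relative_affinity("ACG", two_base_psam)

    def test_dinucleotide_terms(self):
        di = np.zeros((1, 16))
        di[0, 4 * 0 + 3] = 0.5  # AT dinucleotide bonus
        p = PSAM(np.zeros((2, 4)), di)
        assert relative_affinity("AT", p) == pytest.approx(np.exp(0.5))
        assert relative_affinity("AC", p) == 1.0


class TestScanSequence:
    def test_per_offset_against_oracle(self, two_base_psam):
        seq = "ACGTT"
        got = scan_sequence(seq, two_base_psam)
        assert got.shape == (4,)
        for j in range(4):
            w = seq[j : j + 2]
            expect = (naive_affinity(w, two_base_psam)
                      + naive_affinity(naive_revcomp(w), two_base_psam))
            assert got[j] == pytest.approx(expect, rel=1e-12)

    def test_palindromic_model_doubles_forward(self):
        # pos0 and pos1 mirror each other under revcomp -> palindromic
        p = PSAM(np.array([[0.0, -1.0, -1.0, -2.0], [-2.0, -1.0, -1.0, 0.0]]))
        assert np.allclose(p.beta_mono, p.reverse_complement().beta_mono)
        seq = "ACGTAG"
        got = scan_sequence(seq, p)
        fwd = np.array([naive_affinity(seq[j : j + 2], p) for j in range(5)])
        np.testing.assert_allclose(got, 2 * fwd, rtol=1e-12)

    def test_all_n_scores_zero(self, two_base_psam):
        assert scan_sequence("NNNN", two_base_psam).tolist() == [0.0, 0.0, 0.0]

    def test_too_short_raises_with_name(self, two_base_psam):
        with pytest.raises(ValueError, match="chrX"):
            scan_sequence(GenomeSequence("chrX", "A"), two_base_psam)

    def test_strand_involution(self, two_base_psam, random_genome):
        """Scanning the revcomp genome mirrors the raw strand-summed vector."""
        fwd = scan_sequence(random_genome, two_base_psam)
        rc = GenomeSequence("rc", naive_revcomp(random_genome.sequence))
        np.testing.assert_allclose(scan_sequence(rc, two_base_psam),
                                   fwd[::-1], rtol=1e-12)


class TestWindowedMax:
    def test_k1_identity(self):
        v = np.array([3.0, 1.0, 2.0])
        np.testing.assert_array_equal(windowed_max(v, 1), v)

    def test_forced_example_with_truncation(self):
        got = windowed_max(np.array([0, 0.2, 0.5, 0.1]), 2)
        np.testing.assert_allclose(got, [0.2, 0.5, 0.5, 0.1])

    def test_matches_naive_sliding_max(self):
        rng = np.random.default_rng(7)
        v = rng.random(100)
        got = windowed_max(v, 7)
        naive = np.array([v[i : min(i + 7, 100)].max() for i in range(100)])
        np.testing.assert_array_equal(got, naive)

    def test_k_below_one_raises(self):
        with pytest.raises(ValueError):
            windowed_max(np.ones(3), 0)


@st.composite
def dna(draw, min_size=30, max_size=120):
    return draw(st.text(alphabet="ACGT", min_size=min_size, max_size=max_size))


class TestBuildAffinityTrack:
    def test_planted_consensus_is_track_max(self, two_base_psam, random_genome):
        seq = random_genome.sequence[:80] + "AT" + random_genome.sequence[80:]
        g = GenomeSequence("c", seq)
        tr = build_affinity_track([g], two_base_psam)
        assert tr["c"].max() == 1.0

    def test_threshold_zeroes_small_values(self):
        # one strong site and one site below threshold after normalization
        beta = np.zeros((2, 4))
        beta[0] = [0, -10, -10, -10]
        beta[1] = [-10, -10, -10, 0]
        p = PSAM(beta)
        g = GenomeSequence("c", "ATGGGGGGCT")  # CT ~ e^-10 of AT
        tr = build_affinity_track([g], p, threshold=1e-4)
        assert tr["c"][8] == 0.0  # e^-10 ~ 4.5e-5 < 1e-4
        assert tr["c"][0] == 1.0

    def test_oracle_equivalence_exact(self, random_genome):
        rng = np.random.default_rng(5)
        beta = PSAM.normalize_mono(rng.uniform(-3, 0, size=(7, 4)))
        p = PSAM(beta)
        tr = build_affinity_track([random_genome], p)
        expect, raw_max = naive_track([random_genome], p)
        np.testing.assert_array_equal(tr[random_genome.name],
                                      expect[random_genome.name])
        assert tr.raw_max == raw_max

    def test_multicontig_normalized_to_global_max(self, two_base_psam):
        g1 = GenomeSequence("c1", "ATATAT")
        g2 = GenomeSequence("c2", "GGGGGG")
        tr = build_affinity_track([g1, g2], two_base_psam)
        assert tr["c1"].max() == 1.0
        assert tr["c2"].max() < 1.0

    def test_all_n_genome_raises(self, two_base_psam):
        with pytest.raises(ValueError, match="no scorable window"):
            build_affinity_track([GenomeSequence("c", "NNNNNN")], two_base_psam)

    @settings(max_examples=20, deadline=None)
    @given(seq=dna())
    def test_property_oracle_and_normalization(self, seq):
        """For any short genome, the track equals the enumeration oracle
        bit-for-bit and its global max is exactly 1."""
        rng = np.random.default_rng(11)
        p = PSAM(PSAM.normalize_mono(rng.uniform(-2, 0, size=(5, 4))))
        g = GenomeSequence("c", seq)
        tr = build_affinity_track([g], p)
        expect, _ = naive_track([g], p)
        np.testing.assert_array_equal(tr["c"], expect["c"])
        assert tr["c"].max() == 1.0

    def test_mono_shift_invariance(self, random_genome):
        rng = np.random.default_rng(9)
        raw = rng.uniform(-3, 0, size=(5, 4))
        p1 = PSAM(PSAM.normalize_mono(raw))
        p2 = PSAM(PSAM.normalize_mono(raw + np.array([0, 1.7, 0, 0, 0])[:, None]))
        t1 = build_affinity_track([random_genome], p1)
        t2 = build_affinity_track([random_genome], p2)
        np.testing.assert_allclose(t1[random_genome.name],
                                   t2[random_genome.name], rtol=1e-12)


class TestTopMotifs:
    def test_planted_consensus_ranks_first(self, two_base_psam):
        hits = top_motifs("GGGGATGGGG", two_base_psam, n=3)
        assert hits[0].offset == 4 and hits[0].strand == "+"
        assert hits[0].relative_affinity == 1.0

    def test_returns_ten_rows(self, two_base_psam):
        seq = "ACGTAGCTAGGATCCGATCGAATTCCGGAT"
        assert len(top_motifs(seq, two_base_psam, n=10)) == 10

    def test_full_list_matches_enumeration_oracle(self, two_base_psam):
        seq = "ACGTAGCTAGGATCCGATCG"
        hits = top_motifs(seq, two_base_psam, n=10_000)
        oracle = []
        for j in range(len(seq) - 1):
            w = seq[j : j + 2]
            for strand, ww in (("+", w), ("-", naive_revcomp(w))):
                a = naive_affinity(ww, two_base_psam)
                if a > 0:
                    oracle.append((j, strand, a))
        denom = max(a for _, _, a in oracle)
        oracle = sorted(((a / denom, j, s) for j, s, a in oracle),
                        key=lambda t: (-t[0], t[1], t[2]))
        got = [(h.relative_affinity, h.offset, h.strand) for h in hits]
        for (ea, ej, es), (ga, gj, gs) in zip(oracle, got):
            assert (ej, es) == (gj, gs) and ga == pytest.approx(ea, rel=1e-12)

    def test_genomic_max_normalization(self, two_base_psam):
        hits = top_motifs("GGATGG", two_base_psam, n=1, genomic_max=2.0)
        assert hits[0].relative_affinity == pytest.approx(0.5)


class TestPsamIO:
    def test_roundtrip(self, tmp_path, two_base_psam):
        p = tmp_path / "m.psam"
        write_psam(two_base_psam, p)
        back = read_psam(p)
        np.testing.assert_allclose(back.beta_mono, two_base_psam.beta_mono)
        assert back.mode_id == two_base_psam.mode_id

    def test_roundtrip_with_dinucleotides(self, tmp_path):
        rng = np.random.default_rng(2)
        p = PSAM(PSAM.normalize_mono(rng.uniform(-2, 0, (3, 4))),
                 rng.uniform(-1, 1, (2, 16)), mode_id="dim")
        f = tmp_path / "m.psam"
        write_psam(p, f)
        back = read_psam(f)
        np.testing.assert_allclose(back.beta_mono, p.beta_mono)
        np.testing.assert_allclose(back.beta_di, p.beta_di)

    def test_read_renormalizes_shifted_file(self, tmp_path, random_genome):
        f = tmp_path / "m.psam"
        f.write_text("#PSAM k=2 mode_id=x dinuc=0\n"
                     "1.0 0.0 -1.0 -2.0\n0.0 0.0 0.0 1.0\n")
        p = read_psam(f)
        assert np.allclose(p.beta_mono.max(axis=1), 0.0)
        # relative window ordering is shift-invariant
        ref = PSAM(PSAM.normalize_mono(
            np.array([[1.0, 0.0, -1.0, -2.0], [0.0, 0.0, 0.0, 1.0]])))
        np.testing.assert_allclose(
            scan_sequence(random_genome, p),
            scan_sequence(random_genome, ref), rtol=1e-12)

    def test_wrong_column_count_rejected(self, tmp_path):
        f = tmp_path / "m.psam"
        f.write_text("#PSAM k=2 mode_id=x dinuc=0\n0 0 0\n0 0 0 0\n")
        with pytest.raises(ValueError, match="columns"):
            read_psam(f)
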