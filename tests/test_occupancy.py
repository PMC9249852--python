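import numpy as np
import pandas as pd
import pytest

from parabind.occupancy import (annotate_locus, consensus_loci, locus_score,
                                pearson, scaling_factor, signal_matrix,
                                union_loci)
from parabind.types import ConsensusLocus, CoverageTrack, Interval, PeakSet


def _sets(*peak_lists):
    return [PeakSet(f"s{i}", list(pl)) for i, pl in enumerate(peak_lists)]


class TestConsensusLoci:
    def test_full_agreement_single_locus(self):
        pk = lambda: Interval("c", 900, 1100, summit=1000)
        loci = consensus_loci(_sets([pk()], [pk()], [pk()], [pk()]),
                              min_overlap=2)
        assert len(loci) == 1
        assert loci[0].membership == (True, True, True, True)
        assert loci[0].center == 1000
        assert (loci[0].interval.start, loci[0].interval.end) == (750, 1251)

    def test_single_support_excluded(self):
        loci = consensus_loci(
            _sets([Interval("c", 900, 1100, summit=1000)], [], [], []),
            min_overlap=2)
        assert loci == []

    def test_overlapping_windows_merge_with_mean_center(self):
        loci = consensus_loci(
            _sets([Interval("c", 900, 1100, summit=1000)],
                  [Interval("c", 1300, 1500, summit=1400)]),
            min_overlap=2)
        # 501-bp windows [750,1251) and [1150,1651) overlap -> one locus
        assert len(loci) == 1 and loci[0].center == 1200

    def test_non_overlapping_windows_stay_separate(self):
        loci = consensus_loci(
            _sets([Interval("c", 900, 1100, summit=1000)],
                  [Interval("c", 1900, 2100, summit=2000)],
                  [Interval("c", 880, 1080, summit=1001)],
                  [Interval("c", 1880, 2080, summit=2003)]),
            min_overlap=2)
        assert len(loci) == 2
        assert [lo.center for lo in loci] == [1000, 2001]

    def test_summitless_peak_uses_midpoint(self):
        loci = consensus_loci(
            _sets([Interval("c", 900, 1100)], [Interval("c", 900, 1100)]),
            min_overlap=2)
        assert loci[0].center == 1000

    def test_permutation_invariance(self):
        sets = _sets([Interval("c", 900, 1100, summit=1000)],
                     [Interval("c", 1300, 1500, summit=1400)],
                     [Interval("c", 5000, 5200, summit=5100)])
        a = consensus_loci(sets, min_overlap=1)
        b = consensus_loci(sets[::-1], min_overlap=1)
        assert [(lo.center, lo.n_members) for lo in a] == [
            (lo.center, lo.n_members) for lo in b]
        assert [lo.membership[::-1] for lo in a] == [lo.membership for lo in b]

    def test_union_loci_disjoint_sets_empty(self):
        loci = union_loci(_sets([Interval("c", 900, 1100, summit=1000)],
                                [Interval("c", 9000, 9200, summit=9100)]),
                          min_overlap=2)
        assert loci == []

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError):
            consensus_loci(_sets([Interval("c", 1, 10)]))


class TestLocusScore:
    def test_uniform_coverage_sums_100(self):
        tr = CoverageTrack({"c": np.ones(1000)})
        assert locus_score(tr, "c", 500) == 100.0

    def test_step_function(self):
        vec = np.zeros(1000)
        vec[490:510] = 2.0
        assert locus_score(CoverageTrack({"c": vec}), "c", 500) == 40.0

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(3)
        vec = rng.random(400)
        got = locus_score(CoverageTrack({"c": vec}), "c", 200)
        assert got == pytest.approx(vec[150:250].sum())

    def test_truncated_window_warns(self):
        tr = CoverageTrack({"c": np.ones(60)})
        with pytest.warns(UserWarning, match="truncated"):
            assert locus_score(tr, "c", 30) == 60.0

    def test_center_outside_contig_raises(self):
        with pytest.raises(ValueError):
            locus_score(CoverageTrack({"c": np.ones(10)}), "c", 50)

    def test_additive_over_track_decomposition(self):
        rng = np.random.default_rng(8)
        a, b = rng.random(300), rng.random(300)
        s = (locus_score(CoverageTrack({"c": a}), "c", 150)
             + locus_score(CoverageTrack({"c": b}), "c", 150))
        assert s == pytest.approx(
            locus_score(CoverageTrack({"c": a + b}), "c", 150))


class TestScalingFactor:
    def test_two_point_case(self):
        a = pd.Series({"l1": 10.0, "l2": 10.0})
        b = pd.Series({"l1": 20.0, "l2": 20.0})
        f = scaling_factor(a, b, ["l1", "l2"])
        assert f == 0.5
        assert (b * f).mean() == a.mean()

    def test_identical_samples_give_one(self):
        a = pd.Series({"l1": 3.0, "l2": 7.0})
        assert scaling_factor(a, a, ["l1", "l2"]) == 1.0

    def test_equalizes_means_to_machine_precision(self):
        rng = np.random.default_rng(4)
        ids = [f"l{i}" for i in range(50)]
        a = pd.Series(rng.random(50) * 10, index=ids)
        b = pd.Series(rng.random(50) * 3 + 1, index=ids)
        f = scaling_factor(a, b, ids)
        assert (b.loc[ids] * f).mean() == pytest.approx(a.loc[ids].mean(),
                                                        rel=1e-14)

    def test_empty_shared_set_rejected(self):
        with pytest.raises(ValueError):
            scaling_factor(pd.Series(dtype=float), pd.Series(dtype=float), [])


def _locus(center, contig="c"):
    return ConsensusLocus(
        interval=Interval(contig, max(0, center - 250), center + 251,
                          summit=center),
        center=center, membership=(True, True), locus_id=f"L{center}")


class TestSignalMatrix:
    def test_exactly_100_bins_at_printed_parameters(self):
        tr = CoverageTrack({"c": np.ones(4000)})
        m = signal_matrix([_locus(2000)], tr, halfwidth=1000, binsize=20)
        assert m.shape == (1, 100)

    def test_uniform_track_constant_matrix(self):
        tr = CoverageTrack({"c": np.full(4000, 2.5)})
        m = signal_matrix([_locus(2000)], tr)
        np.testing.assert_allclose(m, 2.5)

    def test_triangular_bump_argmax_at_center_bins(self):
        vec = np.zeros(4000)
        d = np.arange(-249, 250)
        vec[2000 - 249 : 2000 + 250] = 1 - np.abs(d) / 250
        m = signal_matrix([_locus(2000)], CoverageTrack({"c": vec}))
        assert m[0].argmax() in (49, 50)
        # direct binning oracle
        w = vec[1000:3000]
        expect = w.reshape(100, 20).mean(axis=1)
        np.testing.assert_allclose(m[0], expect)

    def test_row_mean_conserved_under_binning(self):
        rng = np.random.default_rng(6)
        vec = rng.random(4000)
        m = signal_matrix([_locus(2000)], CoverageTrack({"c": vec}))
        assert m[0].mean() == pytest.approx(vec[1000:3000].mean())

    def test_offcontig_window_truncated(self):
        # center 100 on a 500-bp contig: the +/-1 kb window runs off both
        # edges; bins fully outside are 0, covered bins average the signal
        tr = CoverageTrack({"c": np.ones(500)})
        m = signal_matrix([_locus(100)], tr)
        assert m[0, 0] == 0.0 and m[0, 99] == 0.0 and m[0, 50] == 1.0

    def test_binsize_must_divide(self):
        with pytest.raises(ValueError):
            signal_matrix([], CoverageTrack({}), halfwidth=1000, binsize=21)


class TestAnnotateLocus:
    @pytest.fixture
    def genes(self):
        return pd.DataFrame({
            "contig": ["c", "c"],
            "strand": ["+", "-"],
            "start": [5000, 1000],
            "end": [9000, 2000],
            "tss": [5000, 1999],
            "tts": [8999, 1000],
            "exons": [[(5000, 5500), (8000, 9000)], [(1000, 2000)]],
        }, index=["gp", "gm"])

    def test_plus_strand_promoter(self, genes):
        gp_only = genes.loc[["gp"]]
        assert annotate_locus(4200, "c", gp_only) == "TSS"

    def test_minus_strand_promoter_upstream(self, genes):
        assert annotate_locus(2500, "c", genes.loc[["gm"]]) == "TSS"

    def test_intergenic_far_from_genes(self, genes):
        assert annotate_locus(50_000, "c", genes) == "intergenic"

    def test_intron_inside_gene_body(self, genes):
        assert annotate_locus(7000, "c", genes.loc[["gp"]]) == "intron"

    def test_every_center_gets_exactly_one_label(self, genes):
        labels = {annotate_locus(c, "c", genes)
                  for c in range(0, 12_000, 137)}
        assert labels <= {"TSS", "TTS", "exon", "intron", "intergenic"}


class TestPearson:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        assert pearson(x, x) == pytest.approx(1.0)

    def test_anti_correlation(self):
        x = np.arange(10.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])
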