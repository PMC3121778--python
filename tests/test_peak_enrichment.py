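import math

import numpy as np
import pytest

from hydroxyscape.genome_io import GenomeAssembly, GenomicInterval, IntervalSet
from hydroxyscape.peak_enrichment import (
    Peak,
    PeakCallParams,
    call_peaks,
    feature_association,
    overlap_percentages,
    peaks_to_interval_set,
    poisson_upper_tail,
    set_overlap,
)

from conftest import make_tags


def exact_poisson_tail(k, lam, terms=400):
    """Independent oracle: direct pmf summation with exact accumulation."""
    logs = [i * math.log(lam) - lam - math.lgamma(i + 1) for i in range(k, k + terms)]
    return math.fsum(math.exp(v) for v in logs)


class TestPoissonTail:
    @pytest.mark.parametrize("k,lam", [(20, 2.0), (3, 2.0), (0, 5.0), (7, 0.5), (50, 10.0)])
    def test_matches_pmf_summation(self, k, lam):
        expected = exact_poisson_tail(k, lam)
        got = float(poisson_upper_tail(k, lam))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_window_of_twenty_on_lambda_two_is_significant(self):
        assert float(poisson_upper_tail(20, 2.0)) < 1e-8

    def test_window_of_three_on_lambda_two_is_not(self):
        # sum_{k>=3} e^-2 2^k / k! ~ 0.3233
        assert float(poisson_upper_tail(3, 2.0)) == pytest.approx(0.3233, abs=5e-5)


class TestCallPeaks:
    asm = GenomeAssembly((("chr1", 100_000),))

    def uniform_tags(self, rng, n, L=100_000):
        return make_tags(
            [("chr1", int(p), "+") for p in rng.integers(0, L, n)]
        )

    def cluster(self, rng, center, n, spread=80):
        return [("chr1", int(p), "+") for p in rng.integers(center - spread, center + spread, n)]

    def test_empty_ip_rejected(self):
        import pandas as pd
        from hydroxyscape.genome_io import TagCollection

        empty = TagCollection(pd.DataFrame(columns=["chrom", "start", "strand"]))
        with pytest.raises(ValueError, match="empty"):
            call_peaks(empty, None, self.asm)

    def test_planted_cluster_is_recovered(self):
        rng = np.random.default_rng(5)
        ip = make_tags(
            self.cluster(rng, 50_000, 120)
            + [("chr1", int(p), "+") for p in rng.integers(0, 100_000, 2000)]
        )
        inp = self.uniform_tags(np.random.default_rng(6), 2000)
        peaks = call_peaks(ip, inp, self.asm)
        assert len(peaks) == 1
        pk = peaks[0]
        assert pk.start <= 50_000 <= pk.end
        assert pk.p_value <= 1e-8
        assert pk.start <= pk.summit < pk.end

    def test_distant_clusters_stay_separate(self):
        rng = np.random.default_rng(8)
        ip = make_tags(
            self.cluster(rng, 20_000, 120)
            + self.cluster(rng, 80_000, 120)
            + [("chr1", int(p), "+") for p in rng.integers(0, 100_000, 1000)]
        )
        inp = self.uniform_tags(np.random.default_rng(9), 1000)
        peaks = call_peaks(ip, inp, self.asm)
        assert len(peaks) == 2

    def test_homogeneous_background_yields_no_peaks(self):
        rng = np.random.default_rng(12)
        ip = self.uniform_tags(rng, 5000)
        inp = self.uniform_tags(rng, 5000)
        assert call_peaks(ip, inp, self.asm) == []

    def test_works_without_input_library(self):
        rng = np.random.default_rng(13)
        ip = make_tags(
            self.cluster(rng, 50_000, 150)
            + [("chr1", int(p), "+") for p in rng.integers(0, 100_000, 2000)]
        )
        peaks = call_peaks(ip, None, self.asm)
        assert len(peaks) == 1

    def test_params_validation(self):
        with pytest.raises(ValueError):
            PeakCallParams(p_cutoff=1.5)
        with pytest.raises(ValueError):
            PeakCallParams(bandwidth=5, window_step=10)


class TestFeatureAssociation:
    def test_fold_formula(self):
        asm = GenomeAssembly((("chr1", 1000),))
        feature = IntervalSet("f", (GenomicInterval("chr1", 0, 100),))
        peaks = [GenomicInterval("chr1", 10 * i, 10 * i + 5) for i in range(5)] + [
            GenomicInterval("chr1", 500 + 20 * i, 510 + 20 * i) for i in range(5)
        ]
        report = feature_association(peaks, [feature], asm)
        row = report.loc["f"]
        assert row["observed_fraction"] == pytest.approx(0.5)
        assert row["expected_fraction"] == pytest.approx(0.1)
        assert row["fold_change"] == pytest.approx(5.0)

    def test_whole_genome_feature_saturates_at_fold_one(self):
        asm = GenomeAssembly((("chr1", 1000),))
        everything = IntervalSet("all", (GenomicInterval("chr1", 0, 1000),))
        peaks = [GenomicInterval("chr1", 3, 9), GenomicInterval("chr1", 700, 900)]
        assert feature_association(peaks, [everything], asm).loc["all", "fold_change"] == pytest.approx(1.0)

    def test_zero_coverage_feature_rejected(self):
        asm = GenomeAssembly((("chr1", 1000),))
        with pytest.raises(ValueError):
            feature_association(
                [GenomicInterval("chr1", 0, 5)], [IntervalSet("empty", ())], asm
            )

    def test_random_point_peaks_give_fold_near_one(self):
        # uniformly placed 1-bp peaks: observed overlap fraction converges to
        # the feature's base-coverage fraction, so fold -> 1
        asm = GenomeAssembly((("chr1", 100_000),))
        feature = IntervalSet("f", (GenomicInterval("chr1", 20_000, 30_000),))
        rng = np.random.default_rng(21)
        folds = []
        for _ in range(300):
            pos = rng.integers(0, 100_000, 20)
            peaks = [GenomicInterval("chr1", int(p), int(p) + 1) for p in pos]
            folds.append(feature_association(peaks, [feature], asm).loc["f", "fold_change"])
        assert np.mean(folds) == pytest.approx(1.0, abs=0.15)


def brute_force_overlap_count(a_ivs, b_ivs):
    """Quadratic all-pairs oracle for member-level >=1 bp overlap."""
    n = 0
    for x in a_ivs:
        for y in b_ivs:
            if x.chrom == y.chrom and x.start < y.end and y.start < x.end:
                n += 1
                break
    return n


class TestSetOverlap:
    def iv(self, s, e, chrom="chr1"):
        return GenomicInterval(chrom, s, e)

    def test_one_bp_shared_counts(self):
        r = set_overlap(
            IntervalSet("a", (self.iv(0, 10),)), IntervalSet("b", (self.iv(9, 20),))
        )
        assert r["a_overlapping_b"] == 1 and r["b_overlapping_a"] == 1

    def test_half_open_abutment_does_not_count(self):
        r = set_overlap(
            IntervalSet("a", (self.iv(0, 10),)), IntervalSet("b", (self.iv(10, 20),))
        )
        assert r["a_overlapping_b"] == 0

    def test_triple_overlap_count(self):
        a = IntervalSet("a", (self.iv(0, 10), self.iv(100, 110)))
        b = IntervalSet("b", (self.iv(5, 15), self.iv(105, 115)))
        c = IntervalSet("c", (self.iv(8, 9),))
        r = set_overlap(a, b, c)
        assert r["a_overlapping_b"] == 2
        assert r["a_overlapping_b_and_c"] == 1

    def test_matches_quadratic_oracle_on_random_instances(self):
        rng = np.random.default_rng(31)
        for _ in range(3):
            mk = lambda n: tuple(
                GenomicInterval(
                    f"chr{rng.integers(1, 4)}", int(s), int(s) + int(rng.integers(1, 500))
                )
                for s in rng.integers(0, 50_000, n)
            )
            a, b = IntervalSet("a", mk(500)), IntervalSet("b", mk(500))
            r = set_overlap(a, b)
            assert r["a_overlapping_b"] == brute_force_overlap_count(a.intervals, b.intervals)
            assert r["b_overlapping_a"] == brute_force_overlap_count(b.intervals, a.intervals)


class TestOverlapPercentages:
    @pytest.mark.parametrize(
        "overlapping,total,decimals,expected",
        [
            (1795, 3094, 0, 58.0),
            (1795, 58023, 1, 3.1),
            (166, 3094, 1, 5.4),
            (19973, 58023, 1, 34.4),
            (0, 5, 1, 0.0),
            (1, 8, 0, 13.0),  # 12.5 rounds half-up to 13
        ],
    )
    def test_rounding_half_up(self, overlapping, total, decimals, expected):
        assert overlap_percentages(overlapping, total, decimals) == expected

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            overlap_percentages(1, 0)
        with pytest.raises(ValueError):
            overlap_percentages(5, 3)


class TestPeakObjects:
    def test_summit_must_lie_inside(self):
        with pytest.raises(ValueError):
            Peak(GenomicInterval("c", 0, 10), 1e-9, summit=50, tag_count=3)

    def test_interval_set_export_scores_are_neg_log10_p(self):
        pk = Peak(GenomicInterval("c", 0, 10), 1e-12, summit=5, tag_count=30)
        ivset = peaks_to_interval_set([pk])
        assert ivset.intervals[0].score == pytest.approx(12.0)
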