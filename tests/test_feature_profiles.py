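import numpy as np
import pytest

from hydroxyscape.genome_io import GenomeAssembly, GeneModel, GenomicInterval, IntervalSet
from hydroxyscape.feature_profiles import (
    SegmentLayout,
    anchored_profile,
    classify_bimodal,
    profile_summary,
    scaled_site_profile,
    stratify_by_expression,
    three_segment_profile,
)

from conftest import make_tags

ASM = GenomeAssembly((("chr1", 50_000),))


def gene(tss, strand="+", length=2000, chrom="chr1", rpkm=1.0, name=None):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + length, strand, name=name)
    else:
        iv = GenomicInterval(chrom, tss - length, tss, strand, name=name)
    return GeneModel(iv, rpkm)


class TestStratify:
    def test_quartile_split_by_descending_rpkm(self):
        genes = [gene(1000 + 3000 * i, rpkm=r) for i, r in enumerate([10, 9, 5, 4, 3, 2, 1, 0])]
        s = stratify_by_expression(genes)
        assert s.top25 == (0, 1)
        assert s.bottom25 == (6, 7)

    def test_ties_keep_input_order(self):
        genes = [gene(1000 + 3000 * i, rpkm=5.0) for i in range(8)]
        s = stratify_by_expression(genes)
        assert s.top25 == (0, 1) and s.mid25_50 == (2, 3) and s.bottom25 == (6, 7)

    def test_floor_splits_for_n_not_divisible_by_four(self):
        genes = [gene(1000 + 3000 * i, rpkm=float(5 - i)) for i in range(5)]
        s = stratify_by_expression(genes)
        sizes = tuple(len(g) for g in (s.top25, s.mid25_50, s.mid50_75, s.bottom25))
        assert sizes == (1, 1, 1, 2)

    def test_groups_partition_input(self):
        genes = [gene(1000 + 3000 * i, rpkm=float(i % 3)) for i in range(11)]
        s = stratify_by_expression(genes)
        combined = sorted(s.top25 + s.mid25_50 + s.mid50_75 + s.bottom25)
        assert combined == list(range(11))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_expression([])


class TestAnchoredProfile:
    def test_plus_strand_single_tag_column(self):
        g = gene(5000, "+")
        tags = make_tags([("chr1", 5050, "+")])
        mat = anchored_profile(tags, None, [g], ASM, "TSS", flank=5000, bin_size=100)
        # library of one tag: RPM normalisation scales the single count to 1e6
        assert mat.n_cols == 100
        assert mat.values[0, 50] == pytest.approx(1e6)
        assert np.nansum(mat.values) == pytest.approx(1e6)

    def test_minus_strand_flips_to_same_column(self):
        g = gene(5000, "-")
        tags = make_tags([("chr1", 4950, "+")])
        mat = anchored_profile(tags, None, [g], ASM, "TSS", flank=5000, bin_size=100)
        assert mat.values[0, 50] == pytest.approx(1e6)

    def test_uniform_field_gives_flat_rows(self):
        # ~400 expected tags per 100-bp bin: row CV well under 0.1
        rng = np.random.default_rng(19)
        pos = rng.integers(0, 50_000, 200_000)
        tags = make_tags([("chr1", int(p), "+") for p in pos])
        mat = anchored_profile(tags, None, [gene(25_000, "+")], ASM, "TSS", 2000, 100)
        row = mat.values[0]
        assert np.std(row) / np.mean(row) < 0.1

    def test_out_of_chromosome_bins_are_missing(self):
        g = gene(1000, "+")
        tags = make_tags([("chr1", 100, "+")])
        mat = anchored_profile(tags, None, [g], ASM, "TSS", flank=5000, bin_size=100)
        assert np.isnan(mat.values[0, :40]).all()  # bins before position 0
        assert not np.isnan(mat.values[0, 40:]).any()

    def test_input_subtraction_cancels_identical_libraries(self):
        tags = make_tags([("chr1", 5050, "+"), ("chr1", 7000, "-")])
        mat = anchored_profile(tags, tags, [gene(5000, "+")], ASM, "TSS", 2000, 100)
        assert np.nansum(np.abs(mat.values)) == 0.0

    def test_tes_anchor_for_minus_gene_is_interval_start(self):
        g = gene(10_000, "-", length=2000)  # interval [8000,10000), TES = 8000
        assert g.tes == 8000
        tags = make_tags([("chr1", 8000, "+")])
        mat = anchored_profile(tags, None, [g], ASM, "TES", 1000, 100)
        # tag sits at the anchor: first bin downstream = column 10 pre-flip,
        # and the '-' strand flip maps it to column 20-1-10 = 9
        assert mat.values[0, 9] == pytest.approx(1e6)

    def test_strand_symmetry_under_genome_mirroring(self):
        # mirroring all coordinates and flipping strands leaves profiles identical
        rng = np.random.default_rng(29)
        L = 50_000
        pos = rng.integers(0, L, 5000)
        strands = np.where(rng.random(5000) < 0.5, "+", "-")
        tags = make_tags(list(zip(["chr1"] * 5000, pos, strands)))
        mirrored = make_tags(
            list(zip(["chr1"] * 5000, L - 1 - pos, np.where(strands == "+", "-", "+")))
        )
        genes = [gene(12_000, "+", name="a"), gene(30_000, "-", name="b")]
        genes_m = [
            GeneModel(
                GenomicInterval(
                    "chr1", L - g.interval.end, L - g.interval.start,
                    "-" if g.strand == "+" else "+", name=g.name,
                ),
                g.rpkm,
            )
            for g in genes
        ]
        a = anchored_profile(tags, None, genes, ASM, "TSS", 2000, 100)
        b = anchored_profile(mirrored, None, genes_m, ASM, "TSS", 2000, 100)
        np.testing.assert_allclose(a.values, b.values)


class TestThreeSegment:
    def region(self, center, strand="."):
        return IntervalSet("r", (GenomicInterval("chr1", center - 500, center + 500, strand),))

    def test_column_count_is_120(self):
        tags = make_tags([("chr1", 10_000, "+")])
        mat = three_segment_profile(tags, None, self.region(10_000), ASM)
        assert mat.n_cols == 120
        assert SegmentLayout().n_cols == 120

    def test_tag_at_center_lands_in_first_right_of_center_column(self):
        tags = make_tags([("chr1", 10_000, "+")])
        mat = three_segment_profile(tags, None, self.region(10_000), ASM)
        assert mat.values[0, 60] == pytest.approx(1e6)

    def test_core_boundary_is_half_open(self):
        tags = make_tags([("chr1", 8_000, "+")])  # exactly center - 2000
        mat = three_segment_profile(tags, None, self.region(10_000), ASM)
        assert mat.values[0, 40] == pytest.approx(1e6)

    def test_center_near_edge_yields_missing_flank_columns(self):
        tags = make_tags([("chr1", 4_000, "+")])
        mat = three_segment_profile(tags, None, self.region(4_000), ASM)
        assert np.isnan(mat.values[0, :20]).all()

    def test_mismatched_layout_rejected(self):
        with pytest.raises(ValueError):
            SegmentLayout(core_width=4000, core_bin=300)


class TestScaledProfile:
    def site(self, start, end, strand="."):
        return IntervalSet("s", (GenomicInterval("chr1", start, end, strand),))

    def test_within_site_portion_indexing(self):
        tags = make_tags([("chr1", 10_005, "+")])
        mat = scaled_site_profile(tags, None, self.site(10_000, 10_400), ASM)
        # offset 5 in a 400-bp site: portion floor(40*5/400) = 0 -> column 40
        assert mat.n_cols == 120
        assert mat.values[0, 40] == pytest.approx(1e6)

    def test_fractional_portion_widths(self):
        tags = make_tags([("chr1", 10_005, "+")])
        mat = scaled_site_profile(tags, None, self.site(10_000, 10_100), ASM)
        # 100-bp site: portion floor(40*5/100) = 2 -> column 42
        assert mat.values[0, 42] == pytest.approx(1e6)

    def test_within_site_mass_conservation(self):
        rng = np.random.default_rng(37)
        inside = [("chr1", int(p), "+") for p in rng.integers(10_000, 10_400, 300)]
        outside = [("chr1", int(p), "+") for p in rng.integers(30_000, 40_000, 700)]
        tags = make_tags(inside + outside)
        mat = scaled_site_profile(tags, None, self.site(10_000, 10_400), ASM)
        within = mat.values[0, 40:80]
        assert np.nansum(within) == pytest.approx(300 / (1000 / 1e6))

    def test_minus_strand_site_is_flipped(self):
        tags = make_tags([("chr1", 10_005, "+")])
        fwd = scaled_site_profile(tags, None, self.site(10_000, 10_400, "+"), ASM)
        rev = scaled_site_profile(tags, None, self.site(10_000, 10_400, "-"), ASM)
        np.testing.assert_allclose(fwd.values[0], rev.values[0][::-1])


class TestSummaryAndClassifier:
    def test_mean_of_identical_rows_is_the_row(self):
        tags = make_tags([("chr1", 10_000, "+")])
        regions = IntervalSet(
            "r",
            (
                GenomicInterval("chr1", 9_500, 10_500),
                GenomicInterval("chr1", 9_500, 10_500),
            ),
        )
        mat = three_segment_profile(tags, None, regions, ASM)
        np.testing.assert_allclose(profile_summary(mat), mat.values[0])

    def test_columnwise_mean(self):
        from hydroxyscape.feature_profiles import ProfileMatrix

        mat = ProfileMatrix(np.array([[0.0, 2.0], [2.0, 0.0]]), ("a", "b"), "TSS", 100)
        np.testing.assert_allclose(profile_summary(mat), [1.0, 1.0])

    def test_missing_values_ignored_in_mean(self):
        from hydroxyscape.feature_profiles import ProfileMatrix

        mat = ProfileMatrix(np.array([[1.0, np.nan], [3.0, np.nan]]), ("a", "b"), "TSS", 100)
        curve = profile_summary(mat)
        assert curve[0] == pytest.approx(2.0)
        assert np.isnan(curve[1])

    def test_classifier_separates_planted_shapes(self, small_study):
        s = small_study
        cfg = s["config"]
        for key, expect in (("promoters_P1", True), ("promoters_P2", False)):
            mat = three_segment_profile(s["ip"], s["input"], s["features"][key], s["assembly"])
            calls = classify_bimodal(mat, flank_offset_bp=cfg.tss_peak_offset)
            frac = calls.mean()
            assert (frac > 0.9) if expect else (frac < 0.1)
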