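"""Feature catalogs, interval IO, peak collapsing, fragment counting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hmcseal.features import (
    Fragment,
    FeatureCatalog,
    GenomicInterval,
    collapse_peaks,
    count_fragments,
    derive_features,
    filter_low_counts,
    load_intervals,
    metaprofile,
    split_by_genome_tag,
)
from hmcseal.features import CountMatrix
import pandas as pd


class TestLoadIntervals:
    def test_bed_six_columns(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t100\t200\tg1\t0\t+\n")
        (iv,) = load_intervals(p, "bed")
        assert (iv.chrom, iv.start, iv.end, iv.id, iv.strand) == ("chr1", 100, 200, "g1", "+")

    def test_gff_converts_to_zero_based_half_open(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("chr1\tsrc\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        (iv,) = load_intervals(p, "gff")
        assert (iv.start, iv.end, iv.id) == (100, 200, "g1")

    def test_degenerate_record_names_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t200\tok\n" + "chr1\t300\t300\tempty\n")
        with pytest.raises(ValueError, match=":2:"):
            load_intervals(p, "bed")


class TestDeriveFeatures:
    def test_promoter_conventions_and_cpg_clipping(self):
        genes = [
            GenomicInterval("chr1", 5000, 9000, "gp", "+"),
            GenomicInterval("chr1", 5000, 9000, "gm", "-"),
        ]
        cpg = [GenomicInterval("chr1", 500, 700, "c1")]
        cat = derive_features(genes, cpg)
        proms = {p.id: p for p in cat.intervals("promoters")}
        assert (proms["gp_prom"].start, proms["gp_prom"].end) == (2000, 5000)
        assert (proms["gm_prom"].start, proms["gm_prom"].end) == (9000, 12000)
        (ext,) = cat.intervals("cpg_islands")
        assert (ext.start, ext.end) == (0, 1700)

    def test_unstranded_gene_rejected(self):
        with pytest.raises(ValueError, match="promoter"):
            derive_features([GenomicInterval("chr1", 0, 10, "g", ".")])


class TestCollapsePeaks:
    def test_nearby_merged_distant_kept(self):
        near = [GenomicInterval("chr1", 0, 100, "a"), GenomicInterval("chr1", 120, 200, "b")]
        merged = collapse_peaks(near, gap_bp=150)
        assert len(merged) == 1 and (merged[0].start, merged[0].end) == (0, 200)
        far = [GenomicInterval("chr1", 0, 100, "a"), GenomicInterval("chr1", 260, 300, "b")]
        assert len(collapse_peaks(far, gap_bp=150)) == 2

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            collapse_peaks([], gap_bp=-1)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 300)), min_size=1, max_size=40),
           st.randoms(use_true_random=False))
    def test_idempotent_and_order_independent(self, raw, rnd):
        ivals = [GenomicInterval("chr1", s, s + w, f"i{k}") for k, (s, w) in enumerate(raw)]
        once = collapse_peaks(ivals, gap_bp=150)
        twice = collapse_peaks(once, gap_bp=150)
        assert [(i.start, i.end) for i in once] == [(i.start, i.end) for i in twice]
        shuffled = list(ivals)
        rnd.shuffle(shuffled)
        other = collapse_peaks(shuffled, gap_bp=150)
        assert [(i.start, i.end) for i in once] == [(i.start, i.end) for i in other]
        # no remaining pair violates the gap rule
        for a, b in zip(once, once[1:]):
            assert b.start - a.end >= 150


class TestCountFragments:
    def make_catalog(self):
        cat = FeatureCatalog()
        cat.add_category(
            "genes",
            [GenomicInterval("chr1", 100, 200, "f1"), GenomicInterval("chr1", 300, 400, "f2")],
        )
        return cat

    def test_single_overlap_and_mapq_threshold(self):
        cat = self.make_catalog()
        frags = [
            Fragment("chr1", 150, 160, 30, "s1"),
            Fragment("chr1", 150, 160, 9, "s1"),  # below MAPQ 10
        ]
        out = count_fragments(frags, cat)["genes"]
        assert out.counts.loc["f1", "s1"] == 1
        assert out.counts.loc["f2", "s1"] == 0

    def test_overlapping_features_each_incremented(self):
        cat = FeatureCatalog()
        cat.add_category(
            "genes",
            [GenomicInterval("chr1", 100, 300, "wide"), GenomicInterval("chr1", 150, 200, "narrow")],
        )
        out = count_fragments([Fragment("chr1", 160, 170, 60, "s1")], cat)["genes"]
        assert out.counts["s1"].tolist() == [1, 1]

    def test_unknown_chromosome_skipped_not_error(self):
        cat = self.make_catalog()
        out = count_fragments(
            [Fragment("chrUn", 0, 10, 60, "s1"), Fragment("chr1", 150, 160, 60, "s1")], cat
        )["genes"]
        assert out.counts["s1"].sum() == 1

    def test_counts_match_brute_force_overlap_scan(self):
        rng = np.random.default_rng(42)
        feats = []
        pos = 0
        for i in range(10):
            pos += int(rng.integers(0, 100))
            w = int(rng.integers(20, 200))
            feats.append(GenomicInterval("chr1", pos, pos + w, f"f{i}"))
            pos += w - int(rng.integers(0, 50))  # allow overlaps
        feats = [f for f in feats]
        cat = FeatureCatalog()
        cat.add_category("c", feats)
        frags = [
            Fragment("chr1", int(s), int(s) + int(rng.integers(30, 180)), 60, "s1")
            for s in rng.integers(0, pos, size=50)
        ]
        out = count_fragments(frags, cat)["c"].counts["s1"]
        feats_sorted = cat.intervals("c")
        for fi, feat in enumerate(feats_sorted):
            expected = sum(
                1 for fr in frags if fr.start < feat.end and feat.start < fr.end
            )
            assert out.iloc[fi] == expected

    def test_disjoint_features_conserve_fragments(self):
        cat = self.make_catalog()
        rng = np.random.default_rng(1)
        frags = [
            Fragment("chr1", int(s), int(s) + 20, 60, "s1")
            for s in rng.integers(0, 500, size=100)
        ]
        out = count_fragments(frags, cat)["genes"]
        assert out.counts["s1"].sum() <= 100


class TestFilterLowCounts:
    def test_strictly_greater_than_threshold(self):
        df = pd.DataFrame(
            {"a": [10, 11], "b": [10, 11], "c": [10, 11]}, index=["at", "above"]
        )
        kept = filter_low_counts(CountMatrix(df), mean_min=10).counts
        assert list(kept.index) == ["above"]

    def test_all_filtered_allowed(self):
        df = pd.DataFrame({"a": [1], "b": [2]}, index=["low"])
        assert filter_low_counts(CountMatrix(df), mean_min=10).counts.empty


class TestSplitByGenomeTag:
    def test_proportion(self):
        frags = [Fragment("hs_chr1", 0, 10, 60) for _ in range(80)] + [
            Fragment("mm_chr1", 0, 10, 60) for _ in range(20)
        ]
        hs, mm, prop = split_by_genome_tag(frags)
        assert (len(hs), len(mm)) == (80, 20)
        assert prop == pytest.approx(0.8)

    def test_all_human_and_empty(self):
        frags = [Fragment("hs_chr1", 0, 10, 60)]
        assert split_by_genome_tag(frags)[2] == 1.0
        with pytest.raises(ValueError):
            split_by_genome_tag([])

    def test_unprefixed_chromosome_listed(self):
        with pytest.raises(ValueError, match="chrX"):
            split_by_genome_tag([Fragment("chrX", 0, 10, 60)])


class TestMetaprofile:
    def test_bin_count_and_flat_profile_under_uniform_fragments(self):
        rng = np.random.default_rng(5)
        feats = [
            GenomicInterval("chr1", s, s + 3000, f"f{i}", "+")
            for i, s in enumerate(range(10_000, 90_000, 5000))
        ]
        starts = rng.integers(5_000, 95_000, size=20_000)
        frags = [Fragment("chr1", int(s), int(s) + 100, 60, "s1") for s in starts]
        prof = metaprofile(frags, feats, n_bins=10, flank_bp=500, n_flank_bins=5)
        assert len(prof) == 10 + 2 * 5
        assert prof.std() / prof.mean() < 0.10

    def test_flanks_empty_when_fragments_inside_features(self):
        feats = [GenomicInterval("chr1", 1000, 4000, "f0", "+")]
        frags = [Fragment("chr1", 2000, 2100, 60, "s1") for _ in range(50)]
        prof = metaprofile(frags, feats, n_bins=6, flank_bp=500, n_flank_bins=4)
        assert prof[:4].sum() == 0 and prof[-4:].sum() == 0
        assert prof[4:-4].sum() > 0

    def test_short_features_skipped(self):
        feats = [
            GenomicInterval("chr1", 0, 4, "tiny", "+"),
            GenomicInterval("chr1", 1000, 2000, "ok", "+"),
        ]
        prof = metaprofile([Fragment("chr1", 1500, 1600, 60)], feats, n_bins=6, flank_bp=0)
        assert len(prof) == 6
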