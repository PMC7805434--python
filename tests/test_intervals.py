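"""Interval algebra, peak/TSS parsing and region-set comparison."""

import numpy as np
import pytest

from consreg.intervals import (
    GenomicInterval,
    PeakRecord,
    compare_region_sets,
    coverage_segments,
    intersect_intervals,
    merge_intervals,
    nearest_gene,
    subtract_intervals,
    total_length,
)
from consreg.io import (
    PeakParseError,
    filter_peaks_by_pvalue,
    read_peaks,
    read_sample_sheet,
    read_tss,
)

from conftest import assert_sorted_disjoint, base_set, random_track


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestGenomicInterval:
    def test_rejects_degenerate_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_total_lexicographic_order(self):
        ivs = [iv("chr2", 0, 5), iv("chr1", 5, 9), iv("chr1", 5, 6), iv("chr1", 0, 9)]
        assert sorted(ivs) == [
            iv("chr1", 0, 9),
            iv("chr1", 5, 6),
            iv("chr1", 5, 9),
            iv("chr2", 0, 5),
        ]


class TestPeakIO:
    def _write(self, tmp_path, lines, name="peaks.narrowPeak"):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_narrowpeak_cardinality_and_sorting(self, tmp_path):
        p = self._write(
            tmp_path,
            [
                "chr2\t10\t20\tp1\t0\t.\t4\t3.5\t2\t5",
                "chr1\t100\t200\tp2\t0\t.\t4\t2.0\t2\t50",
                "chr1\t5\t50\tp3\t0\t.\t4\t8.0\t2\t20",
            ],
        )
        peaks = read_peaks(p, "narrow")
        assert len(peaks) == 3
        assert [pk.interval.chrom for pk in peaks] == ["chr1", "chr1", "chr2"]
        assert peaks[0].interval == iv("chr1", 5, 50)
        assert peaks[0].neg_log10_p == 8.0

    def test_broadpeak_pvalue_column_mapping(self, tmp_path):
        p = self._write(tmp_path, ["chr1\t0\t100\tp\t0\t.\t7.1\t13.2\t5.0"], "b.broadPeak")
        peaks = read_peaks(p, "broad")
        assert peaks[0].neg_log10_p == 13.2

    def test_missing_pvalue_sentinel(self, tmp_path):
        p = self._write(tmp_path, ["chr1\t0\t100\tp\t0\t.\t7.1\t-1\t5.0"], "b.broadPeak")
        assert read_peaks(p, "broad")[0].neg_log10_p is None

    def test_degenerate_interval_is_error_with_line_number(self, tmp_path):
        p = self._write(tmp_path, ["chr1\t5\t5\tp\t0\t.\t1\t1\t1\t1"])
        with pytest.raises(PeakParseError, match="line 1"):
            read_peaks(p, "narrow")

    def test_malformed_line_names_line_number(self, tmp_path):
        p = self._write(
            tmp_path, ["chr1\t0\t10\tp\t0\t.\t1\t1\t1\t1", "chr1\tnotanint\t20"]
        )
        with pytest.raises(PeakParseError, match="line 2"):
            read_peaks(p, "narrow")

    def test_unknown_format_rejected(self, tmp_path):
        p = self._write(tmp_path, ["chr1\t0\t10"])
        with pytest.raises(ValueError, match="format"):
            read_peaks(p, "gapped")


class TestPvalueFilter:
    def _peak(self, nlp):
        return PeakRecord(interval=iv("chr1", 0, 10), neg_log10_p=nlp)

    def test_strict_inequality_boundary(self):
        peaks = [self._peak(3.0), self._peak(2.0), self._peak(1.0)]
        kept = filter_peaks_by_pvalue(peaks, 0.01)
        # p = 0.001 < 0.01 kept; p = 0.01 equals alpha, excluded; p = 0.1 out
        assert [p.neg_log10_p for p in kept] == [3.0]

    def test_empty_and_alpha_one(self):
        assert filter_peaks_by_pvalue([], 0.05) == []
        peaks = [self._peak(0.5), self._peak(10.0)]
        assert len(filter_peaks_by_pvalue(peaks, 1.0)) == 2

    def test_missing_pvalue_raises(self):
        with pytest.raises(ValueError, match="no reported"):
            filter_peaks_by_pvalue([self._peak(None)], 0.01)


class TestTSS:
    def test_score_filter_keeps_boundary(self, tmp_path):
        p = tmp_path / "tss.bed"
        p.write_text(
            "chr1\t100\t101\tGENE1\t10\nchr1\t200\t201\tGENE2\t9.5\n"
            "chr1\t300\t301\tGENE3\t25\n"
        )
        recs = read_tss(p, min_score=10)
        assert [r.gene for r in recs] == ["GENE1", "GENE3"]

    def test_wide_tss_rejected(self, tmp_path):
        p = tmp_path / "tss.bed"
        p.write_text("chr1\t100\t102\tG\t15\n")
        with pytest.raises(ValueError):
            read_tss(p)


class TestAlgebraExamples:
    def test_merge_overlap_bookend_and_chromosomes(self):
        assert merge_intervals([iv("chr1", 10, 20), iv("chr1", 15, 30)]) == [
            iv("chr1", 10, 30)
        ]
        assert merge_intervals([iv("chr1", 10, 20), iv("chr1", 20, 30)]) == [
            iv("chr1", 10, 30)
        ]
        assert merge_intervals([iv("chr1", 10, 20), iv("chr2", 10, 20)]) == [
            iv("chr1", 10, 20),
            iv("chr2", 10, 20),
        ]

    def test_intersect_examples(self):
        assert intersect_intervals([iv("chr1", 0, 100)], [iv("chr1", 50, 150)]) == [
            iv("chr1", 50, 100)
        ]
        assert intersect_intervals([iv("chr1", 0, 10)], [iv("chr1", 50, 60)]) == []
        a = [iv("chr1", 0, 100), iv("chr1", 50, 120)]
        assert intersect_intervals(a, a) == merge_intervals(a)

    def test_subtract_examples(self):
        assert subtract_intervals([iv("chr1", 0, 100)], [iv("chr1", 40, 60)]) == [
            iv("chr1", 0, 40),
            iv("chr1", 60, 100),
        ]
        a = [iv("chr1", 5, 50)]
        assert subtract_intervals(a, a) == []
        assert subtract_intervals(a, []) == merge_intervals(a)


class TestAlgebraProperties:
    """Exact agreement with per-base membership oracles on random instances."""

    def test_against_per_base_oracle(self, rng):
        for _ in range(300):
            a = random_track(rng)
            b = random_track(rng)
            sa, sb = base_set(a), base_set(b)
            if a:
                merged = merge_intervals(a)
                assert base_set(merged) == sa
                assert_sorted_disjoint(merged)
                # no book-ended neighbours survive a merge
                for x, y in zip(merged, merged[1:]):
                    if x.chrom == y.chrom:
                        assert x.end < y.start
                assert merge_intervals(merged) == merged  # idempotent
            inter = intersect_intervals(a, b)
            assert base_set(inter) == (sa & sb)
            assert_sorted_disjoint(inter)
            diff = subtract_intervals(a, b)
            assert base_set(diff) == (sa - sb)
            assert_sorted_disjoint(diff)
            # partition: (a - b) and (a & b) tile a exactly
            assert base_set(diff) | base_set(inter) == sa
            assert base_set(diff) & base_set(inter) == set()
            # commutativity on covered bases
            assert base_set(intersect_intervals(b, a)) == (sa & sb)

    def test_coverage_segments_against_counting_oracle(self, rng):
        for _ in range(150):
            n_tracks = int(rng.integers(1, 6))
            tracks = [random_track(rng, n_max=5) for _ in range(n_tracks)]
            counts: dict[tuple[str, int], int] = {}
            for t in tracks:
                for base in base_set(t):
                    counts[base] = counts.get(base, 0) + 1
            segs = coverage_segments(tracks)
            seg_counts: dict[tuple[str, int], int] = {}
            for seg, depth in segs:
                for pos in range(seg.start, seg.end):
                    assert (seg.chrom, pos) not in seg_counts
                    seg_counts[(seg.chrom, pos)] = depth
            assert seg_counts == counts


class TestCompareRegionSets:
    def test_self_comparison_is_unity(self):
        a = [iv("chr1", 0, 100), iv("chr2", 5, 60)]
        c = compare_region_sets(a, a)
        assert (c.pct_a_overlapping_b, c.coverage_ratio_a, c.jaccard) == (1, 1, 1)

    def test_disjoint_sets_are_zero(self):
        c = compare_region_sets([iv("chr1", 0, 10)], [iv("chr1", 50, 60)])
        assert (c.pct_a_overlapping_b, c.coverage_ratio_a, c.jaccard) == (0, 0, 0)

    def test_hand_counted_half_overlap(self):
        # overlap 50 bp, A covers 100, union 150
        c = compare_region_sets([iv("chr1", 0, 100)], [iv("chr1", 50, 150)])
        assert c.pct_a_overlapping_b == 1.0
        assert c.coverage_ratio_a == 0.5
        assert c.jaccard == pytest.approx(1 / 3)

    def test_empty_a_flagged_degenerate(self):
        c = compare_region_sets([], [iv("chr1", 0, 10)])
        assert c.degenerate and c.jaccard == 0.0

    def test_jaccard_bounded_by_coverage_ratios(self, rng):
        for _ in range(100):
            a, b = random_track(rng), random_track(rng)
            if not a or not b:
                continue
            ab = compare_region_sets(a, b)
            ba = compare_region_sets(b, a)
            assert ab.jaccard <= min(ab.coverage_ratio_a, ba.coverage_ratio_a) + 1e-12
            assert ab.jaccard == pytest.approx(ba.jaccard)


class TestNearestGene:
    GENES = [
        (iv("chr1", 0, 500), "GENE_LEFT"),
        (iv("chr1", 2000, 3000), "GENE_RIGHT"),
    ]

    def test_overlapping_gene_wins_with_zero_distance(self):
        genes = self.GENES + [(iv("chr1", 1000, 1200), "GENE_IN")]
        assert nearest_gene(iv("chr1", 1050, 1100), genes) == ("GENE_IN", 0)

    def test_hand_computed_distances(self):
        # gaps: 1000-500 = 500 to the left gene, 2000-1100 = 900 to the right
        assert nearest_gene(iv("chr1", 1000, 1100), self.GENES) == ("GENE_LEFT", 500)

    def test_tie_breaks_to_smaller_start(self):
        genes = [(iv("chr1", 0, 100), "A"), (iv("chr1", 300, 400), "B")]
        # CRE 150-250: gap 50 to both
        assert nearest_gene(iv("chr1", 150, 250), genes) == ("A", 50)

    def test_no_gene_on_chromosome(self):
        assert nearest_gene(iv("chrX", 0, 10), self.GENES) is None


class TestSampleSheet:
    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "sheet.tsv"
        p.write_text("path\tmarker\n a\tb\n")
        with pytest.raises(ValueError, match="cell_line"):
            read_sample_sheet(p)


def test_total_length_counts_distinct_bases():
    assert total_length([iv("chr1", 0, 10), iv("chr1", 5, 15)]) == 15


class TestBedtoolsCrossCheck:
    """Independent oracle: BEDTools merge/intersect/subtract defaults."""

    @staticmethod
    def _run_bedtools(sub, tmp_path, a, b=None):
        import subprocess

        def write(path, ivs):
            path.write_text(
                "".join(f"{x.chrom}\t{x.start}\t{x.end}\n" for x in sorted(ivs))
            )

        fa = tmp_path / "a.bed"
        write(fa, a)
        cmd = ["bedtools", sub]
        if sub == "merge":
            cmd += ["-i", str(fa)]
        else:
            fb = tmp_path / "b.bed"
            write(fb, b)
            cmd += ["-a", str(fa), "-b", str(fb)]
        out = subprocess.run(cmd, capture_output=True, text=True, check=True)
        result = []
        for line in out.stdout.splitlines():
            c, s, e = line.split("\t")[:3]
            result.append(iv(c, int(s), int(e)))
        return sorted(result)

    def test_merge_intersect_subtract_agree_with_bedtools(self, rng, tmp_path):
        for trial in range(10):
            a = random_track(rng, n_max=8)
            b = random_track(rng, n_max=8)
            if not a or not b:
                continue
            assert self._run_bedtools("merge", tmp_path, a) == merge_intervals(a)
            got_inter = self._run_bedtools("intersect", tmp_path, a, b)
            assert sorted(base_set(got_inter)) == sorted(
                base_set(intersect_intervals(a, b))
            )
            assert self._run_bedtools("subtract", tmp_path, merge_intervals(a), b) == (
                subtract_intervals(a, b)
            )
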