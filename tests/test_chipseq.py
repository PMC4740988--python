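"""RPM normalization, peak classification, merging, overlap fractions."""

import numpy as np
import pytest

from histoptm.chipseq import (
    CoverageTrack,
    GenomicInterval,
    classify_peaks,
    merge_replicate_peaks,
    overlap_fraction,
    rpm_normalize,
)

from oracles import classify_oracle, merge_oracle, overlap_oracle


def flat_track(value: float, n_bins: int = 100, bin_size: int = 50,
               total: float = 20e6) -> CoverageTrack:
    return CoverageTrack({"chr1": np.full(n_bins, value)}, bin_size, total)


class TestRpm:
    def test_plain_rpm_arithmetic(self):
        t = flat_track(40.0, total=20_000_000)
        out = rpm_normalize(t, scale=1.0)
        assert out.data["chr1"][0] == pytest.approx(2.0)

    def test_default_scale_multiplies_by_ten(self):
        t = flat_track(40.0, total=20_000_000)
        out = rpm_normalize(t)  # scale 10
        assert out.data["chr1"][0] == pytest.approx(20.0)

    def test_empty_track_stays_zero(self):
        t = flat_track(0.0)
        assert rpm_normalize(t).data["chr1"].sum() == 0.0

    def test_zero_mapped_reads_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize(flat_track(1.0, total=0))


class TestClassification:
    def test_uniform_8_vs_1_is_specific_a(self):
        a = flat_track(8.0, total=1)  # already-normalized values
        b = flat_track(1.0, total=1)
        peak = GenomicInterval("chr1", 1000, 2000)
        (c,) = classify_peaks([peak], a, b, pseudocount=0.1)
        assert c.label == "specific_A"
        assert c.max_window_fold == pytest.approx(8.1 / 1.1)

    def test_identical_tracks_constitutive(self):
        a = flat_track(5.0)
        (c,) = classify_peaks([GenomicInterval("chr1", 0, 500)], a, a)
        assert c.label == "constitutive"
        assert c.max_window_fold == pytest.approx(1.0)

    def test_peak_shorter_than_window_single_evaluation(self):
        a, b = flat_track(9.0), flat_track(1.0)
        (c,) = classify_peaks([GenomicInterval("chr1", 100, 140)], a, b)
        assert c.label == "specific_A"

    def test_every_peak_gets_exactly_one_label(self, rng):
        n_bins = 400
        a = CoverageTrack({"chr1": rng.uniform(0, 20, n_bins)}, 50, 1.0)
        b = CoverageTrack({"chr1": rng.uniform(0, 20, n_bins)}, 50, 1.0)
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + int(w))
            for s, w in zip(rng.integers(0, 15000, 30), rng.integers(100, 2000, 30))
        ]
        out = classify_peaks(peaks, a, b)
        assert len(out) == len(peaks)
        assert all(c.label in ("specific_A", "specific_B", "constitutive") for c in out)

    def test_raising_fold_threshold_is_monotone(self, rng):
        n_bins = 400
        a = CoverageTrack({"chr1": rng.uniform(0, 30, n_bins)}, 50, 1.0)
        b = CoverageTrack({"chr1": rng.uniform(0, 30, n_bins)}, 50, 1.0)
        peaks = [
            GenomicInterval("chr1", int(s), int(s) + 600)
            for s in rng.integers(0, 15000, 40)
        ]
        loose = classify_peaks(peaks, a, b, fold=3.0)
        strict = classify_peaks(peaks, a, b, fold=6.0)
        for lo, hi in zip(loose, strict):
            if lo.label == "constitutive":
                assert hi.label == "constitutive"

    def test_matches_exhaustive_window_oracle(self, rng):
        bin_size = 50
        for _ in range(100):
            n_bins = int(rng.integers(20, 120))
            arr_a = rng.uniform(0, 30, n_bins)
            arr_b = rng.uniform(0, 30, n_bins)
            a = CoverageTrack({"chr1": arr_a}, bin_size, 1.0)
            b = CoverageTrack({"chr1": arr_b}, bin_size, 1.0)
            start = int(rng.integers(0, n_bins * bin_size - 300))
            end = start + int(rng.integers(100, 300))
            peak = GenomicInterval("chr1", start, end)
            (c,) = classify_peaks([peak], a, b)
            expected = classify_oracle(
                start, end, arr_a.tolist(), arr_b.tolist(), bin_size, 200, 4.0, 0.1
            )
            assert c.label == expected


class TestMerging:
    def test_overlapping_intervals_coalesce(self):
        out = merge_replicate_peaks(
            [GenomicInterval("chr1", 100, 300)], [GenomicInterval("chr1", 250, 400)]
        )
        assert [(iv.start, iv.end) for iv in out] == [(100, 400)]

    def test_disjoint_inputs_concatenate_sorted(self):
        out = merge_replicate_peaks(
            [GenomicInterval("chr1", 500, 600)], [GenomicInterval("chr1", 100, 200)]
        )
        assert [(iv.start, iv.end) for iv in out] == [(100, 200), (500, 600)]

    def test_book_ended_intervals_join(self):
        out = merge_replicate_peaks(
            [GenomicInterval("chr1", 100, 200)], [GenomicInterval("chr1", 200, 300)]
        )
        assert [(iv.start, iv.end) for iv in out] == [(100, 300)]

    def test_intersection_mode(self):
        out = merge_replicate_peaks(
            [GenomicInterval("chr1", 100, 300)],
            [GenomicInterval("chr1", 250, 400)],
            mode="intersection",
        )
        assert [(iv.start, iv.end) for iv in out] == [(250, 300)]

    def test_matches_base_mask_oracle(self, rng):
        chrom_len = 5000
        for _ in range(100):
            def random_set():
                return [
                    GenomicInterval("chr1", int(s), int(s) + int(w))
                    for s, w in zip(
                        rng.integers(0, chrom_len - 200, rng.integers(1, 12)),
                        rng.integers(1, 200, 12),
                    )
                ]

            r1, r2 = random_set(), random_set()
            got = [(iv.start, iv.end) for iv in merge_replicate_peaks(r1, r2)]
            expected = merge_oracle(
                [(iv.start, iv.end) for iv in r1 + r2], chrom_len
            )
            assert got == expected


class TestOverlapFraction:
    def test_one_of_three_sites_within_1kb(self):
        peaks = [GenomicInterval("chr1", 10_000, 11_000)]
        sites = [
            GenomicInterval("chr1", 11_500, 11_600),   # 500 bp away
            GenomicInterval("chr1", 50_000, 50_100),
            GenomicInterval("chr2", 10_000, 10_100),
        ]
        assert overlap_fraction(sites, peaks) == pytest.approx(1 / 3)

    def test_all_sites_inside_peaks_give_one(self):
        peaks = [GenomicInterval("chr1", 0, 10_000)]
        sites = [GenomicInterval("chr1", s, s + 10) for s in (5, 500, 9000)]
        assert overlap_fraction(sites, peaks) == 1.0

    def test_empty_sites_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            overlap_fraction([], [GenomicInterval("chr1", 0, 10)])

    def test_matches_intervaltree_oracle(self, rng):
        for _ in range(100):
            peaks = [
                GenomicInterval("chr1", int(s), int(s) + int(w))
                for s, w in zip(
                    rng.integers(0, 90_000, 8), rng.integers(100, 1000, 8)
                )
            ]
            sites = [
                GenomicInterval("chr1", int(s), int(s) + 50)
                for s in rng.integers(0, 100_000, 15)
            ]
            got = overlap_fraction(sites, peaks, max_dist=1000)
            expected = overlap_oracle(
                [(s.chrom, s.start, s.end) for s in sites],
                [(p.chrom, p.start, p.end) for p in peaks],
                1000,
            )
            assert got == pytest.approx(expected)
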