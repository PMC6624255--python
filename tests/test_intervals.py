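"""Interval model, narrowPeak I/O and set algebra against brute-force oracles."""

import numpy as np
import pytest

from pioneerscan.intervals import (GenomicInterval, Peak, PeakSet,
                                   merge_intervals, merge_peaksets,
                                   overlap_partition, read_narrowpeak,
                                   write_narrowpeak)


class TestGenomicInterval:
    def test_half_open_length(self):
        assert GenomicInterval("chr1", 100, 200).length == 100

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom="", start=0, end=10),
            dict(chrom="chr1", start=-1, end=10),
            dict(chrom="chr1", start=10, end=10),
            dict(chrom="chr1", start=10, end=5),
            dict(chrom="chr1", start=0, end=10, strand="x"),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GenomicInterval(**kwargs)

    def test_boundary_touching_is_not_overlap(self):
        a = GenomicInterval("chr1", 0, 10)
        b = GenomicInterval("chr1", 10, 20)
        assert not a.overlaps(b) and not b.overlaps(a)
        assert a.overlaps(GenomicInterval("chr1", 9, 11))


class TestNarrowPeakIO:
    def test_field_mapping(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t200\tp1\t50\t.\t8\t5\t3\t25\n")
        peak = read_narrowpeak(p)[0]
        assert (peak.start, peak.end, peak.summit_offset, peak.score) == (100, 200, 25, 50.0)

    def test_negative_summit_falls_back_to_midpoint(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t100\t200\tp1\t50\t.\t8\t5\t3\t-1\n")
        assert read_narrowpeak(p)[0].summit_offset == 50

    def test_bed3_defaults(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t0\t10\n")
        peak = read_narrowpeak(p)[0]
        assert (peak.summit_offset, peak.score) == (5, 0.0)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t0\t10\nchr1\tnope\t20\n")
        with pytest.raises(ValueError, match="line 2"):
            read_narrowpeak(p)

    def test_negative_coordinate_rejected(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t-5\t10\n")
        with pytest.raises(ValueError):
            read_narrowpeak(p)

    def test_round_trip_exact(self, tmp_path, make_peakset):
        ps = make_peakset(50)
        out = tmp_path / "rt.narrowPeak"
        write_narrowpeak(ps, out)
        back = read_narrowpeak(out)
        for a, b in zip(ps, back):
            assert (a.chrom, a.start, a.end, a.name) == (b.chrom, b.start, b.end, b.name)
            assert a.score == b.score and a.summit_offset == b.summit_offset


def brute_force_common(a: PeakSet, b: PeakSet):
    """All-pairs overlap oracle."""
    a_common = {i for i, p in enumerate(a) for q in b if p.interval.overlaps(q.interval)}
    b_common = {j for j, q in enumerate(b) for p in a if q.interval.overlaps(p.interval)}
    return a_common, b_common


class TestOverlapPartition:
    def test_single_overlap(self):
        a = PeakSet([Peak(GenomicInterval("c", 0, 10), 5)], "a")
        b = PeakSet([Peak(GenomicInterval("c", 5, 15), 5)], "b")
        a_only, b_only, common = overlap_partition(a, b)
        assert len(common) == 2 and len(a_only) == len(b_only) == 0

    def test_half_open_boundary(self):
        a = PeakSet([Peak(GenomicInterval("c", 0, 10), 5)], "a")
        b = PeakSet([Peak(GenomicInterval("c", 10, 20), 5)], "b")
        a_only, b_only, common = overlap_partition(a, b)
        assert len(common) == 0 and len(a_only) == len(b_only) == 1

    def test_identical_sets_all_common(self, make_peakset):
        a = make_peakset(20)
        b = PeakSet(list(a.peaks), label="b")
        a_only, b_only, common = overlap_partition(a, b)
        assert len(a_only) == len(b_only) == 0
        assert len(common) == len(a) + len(b)

    def test_counts_conserved_vs_bruteforce(self, rng, make_peakset):
        for _ in range(5):
            a = make_peakset(30)
            b = make_peakset(25)
            a_only, b_only, common = overlap_partition(a, b)
            ac, bc = brute_force_common(a, b)
            assert len(a_only) + len(common) - len(bc) == len(a)
            assert len(common) == len(ac) + len(bc)
            assert len(a_only) == len(a) - len(ac)
            assert len(b_only) == len(b) - len(bc)


def per_base_cover(intervals, contig_len=100_000):
    """Per-base occupancy oracle."""
    occ = np.zeros(contig_len, dtype=bool)
    for iv in intervals:
        occ[iv.start : iv.end] = True
    return occ


class TestMerge:
    def test_overlapping_pair(self):
        a = PeakSet([Peak(GenomicInterval("c", 0, 10), 5)], "a")
        b = PeakSet([Peak(GenomicInterval("c", 5, 15), 5)], "b")
        merged = merge_peaksets([a, b])
        assert [(p.start, p.end) for p in merged] == [(0, 15)]

    def test_idempotent_on_disjoint(self):
        ivs = [GenomicInterval("c", s, s + 10) for s in (0, 20, 40)]
        ps = PeakSet([Peak(iv, 5) for iv in ivs], "a")
        merged = merge_peaksets([ps])
        assert [(p.start, p.end) for p in merged] == [(0, 10), (20, 30), (40, 50)]
        again = merge_peaksets([merged])
        assert [(p.start, p.end) for p in again] == [(p.start, p.end) for p in merged]

    def test_union_cover_matches_per_base_oracle(self, make_peakset):
        ps = make_peakset(100)
        merged = merge_intervals(ps.intervals())
        oracle = per_base_cover(ps.intervals())
        got = per_base_cover(merged)
        assert np.array_equal(oracle, got)
        # merged spans are disjoint and sorted
        for prev, nxt in zip(merged, merged[1:]):
            assert prev.end <= nxt.start
        assert sum(iv.length for iv in merged) <= sum(iv.length for iv in ps.intervals())

    def test_order_invariance(self, rng, make_peakset):
        sets = [make_peakset(15, label=f"s{i}") for i in range(3)]
        fwd = merge_peaksets(sets)
        rev = merge_peaksets(sets[::-1])
        assert [(p.chrom, p.start, p.end) for p in fwd] == [
            (p.chrom, p.start, p.end) for p in rev
        ]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            merge_peaksets([])
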