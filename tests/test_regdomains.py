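"""Regulatory domains, peak-gene assignment and hypergeometric enrichment."""

import math
from fractions import Fraction

import numpy as np
import pytest

from pioneerscan.intervals import GenomicInterval, Peak, PeakSet
from pioneerscan.regdomains import (GeneModel, assign_peaks, build_domains,
                                    hypergeom_two_sided, pattern_enrichment)


def gene(gid, tss, strand="+", chrom="c"):
    return GeneModel(gid, chrom, tss, strand)


def brute_force_domain(g, others, upstream=5000, downstream=1000,
                       max_ext=1_000_000, contig=None):
    """Per-gene linear scan oracle for the basal-plus-extension rule."""
    def basal(x):
        if x.strand == "+":
            lo, hi = x.tss - upstream, x.tss + downstream
        else:
            lo, hi = x.tss - downstream, x.tss + upstream
        return max(lo, 0), hi

    b_lo, b_hi = basal(g)
    ext_lo, ext_hi = max(b_lo - max_ext, 0), b_hi + max_ext
    for other in others:
        if other.chrom != g.chrom:
            continue
        o_lo, o_hi = basal(other)
        if o_lo < b_lo:  # neighbor with basal presence to the left
            ext_lo = max(ext_lo, min(o_hi, b_lo))
        if o_hi > b_hi:  # neighbor with basal presence to the right
            ext_hi = min(ext_hi, max(o_lo, b_hi))
    if contig is not None:
        ext_hi = min(ext_hi, contig)
        b_hi = min(b_hi, contig)
    return (b_lo, b_hi), (min(ext_lo, b_lo), max(ext_hi, b_hi))


class TestBuildDomains:
    def test_lone_plus_gene_worked_example(self):
        [d] = build_domains([gene("g", 2_000_000)])
        assert (d.basal.start, d.basal.end) == (1_995_000, 2_001_000)
        assert (d.extended.start, d.extended.end) == (995_000, 3_001_000)

    def test_extension_stops_at_neighbor_basal_edge(self):
        g1, g2 = gene("g1", 100_000), gene("g2", 150_000)
        d1, d2 = build_domains([g1, g2])
        assert d1.extended.end == 145_000  # g2's basal left edge
        assert d2.extended.start == 101_000  # g1's basal right edge

    def test_minus_strand_basal_mirrored(self):
        [d] = build_domains([gene("g", 2_000_000, strand="-")])
        assert (d.basal.start, d.basal.end) == (1_999_000, 2_005_000)

    def test_domains_clipped_at_contig_end(self):
        [d] = build_domains([gene("g", 50_000)], genome={"c": 60_000})
        assert d.extended.end == 60_000 and d.extended.start == 0

    def test_extension_never_truncates_own_basal(self):
        # overlapping basal domains: extension collapses to zero, not negative
        g1, g2 = gene("g1", 100_000), gene("g2", 103_000)
        d1, d2 = build_domains([g1, g2])
        assert d1.basal.start >= d1.extended.start
        assert d1.basal.end <= d1.extended.end
        assert d2.basal.start >= d2.extended.start

    def test_random_layouts_match_bruteforce_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 12))
            genes = [
                gene(f"g{i}", int(rng.integers(0, 2_000_000)),
                     "+" if rng.random() < 0.5 else "-")
                for i in range(n)
            ]
            domains = build_domains(genes)
            for g, d in zip(genes, domains):
                others = [x for x in genes if x is not g]
                (b_lo, b_hi), (e_lo, e_hi) = brute_force_domain(g, others)
                assert (d.basal.start, d.basal.end) == (b_lo, b_hi), g
                assert (d.extended.start, d.extended.end) == (e_lo, e_hi), g

    def test_extension_flanks_never_enter_neighbor_basal(self, rng):
        # the extension (extended minus basal) stops at neighboring basal
        # domains, so it can never overlap one
        genes = [gene(f"g{i}", int(t)) for i, t in
                 enumerate(sorted(rng.integers(0, 5_000_000, 20)))]
        domains = build_domains(genes)
        for d1 in domains:
            flanks = [
                (d1.extended.start, d1.basal.start),
                (d1.basal.end, d1.extended.end),
            ]
            for d2 in domains:
                if d2.gene_id == d1.gene_id:
                    continue
                for lo, hi in flanks:
                    if lo >= hi:  # empty flank (extension fully clamped)
                        continue
                    assert not (lo < d2.basal.end and d2.basal.start < hi), (
                        d1, d2)


class TestAssignPeaks:
    def peaks_at(self, midpoints, width=200):
        return PeakSet(
            [Peak(GenomicInterval("c", m - width // 2, m + width // 2),
                  width // 2, 1.0, f"p{i}") for i, m in enumerate(midpoints)],
            "peaks",
        )

    def test_midpoint_containment(self):
        domains = build_domains([gene("g1", 1_000_000)])
        assigned, unassigned = assign_peaks(self.peaks_at([1_000_000]), domains)
        assert assigned == {"p0": ["g1"]}
        assert unassigned == []

    def test_multi_assignment_in_overlapping_domains(self):
        domains = build_domains([gene("g1", 100_000), gene("g2", 103_000)])
        # midpoint inside both basal domains
        assigned, _ = assign_peaks(self.peaks_at([100_500]), domains)
        assert assigned == {"p0": ["g1", "g2"]}

    def test_peak_outside_all_domains_unassigned(self):
        domains = build_domains([gene("g1", 1_000_000)], max_extension=10_000)
        assigned, unassigned = assign_peaks(self.peaks_at([5_000_000]), domains)
        assert assigned == {} and unassigned == ["p0"]

    def test_order_invariance(self, rng):
        domains = build_domains(
            [gene(f"g{i}", int(t)) for i, t in enumerate(rng.integers(0, 3_000_000, 15))]
        )
        mids = [int(m) for m in rng.integers(0, 3_000_000, 40)]
        a, _ = assign_peaks(self.peaks_at(mids), domains)
        peaks = self.peaks_at(mids)
        shuffled = PeakSet([peaks[i] for i in rng.permutation(len(peaks))], "s")
        b, _ = assign_peaks(shuffled, domains)
        assert a == b


def enumeration_p(k, n, K, N):
    """Exact-fraction minimum-likelihood two-sided oracle."""
    def pmf(x):
        return Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))

    lo, hi = max(0, n - (N - K)), min(n, K)
    p_obs = pmf(k)
    return float(sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs))


class TestHypergeomTwoSided:
    def test_worked_example(self):
        assert hypergeom_two_sided(4, 4, 5, 10) == pytest.approx(10 / 210)

    def test_mode_gives_p_one(self):
        assert hypergeom_two_sided(2, 4, 5, 10) == pytest.approx(1.0)

    def test_degenerate_full_draw(self):
        assert hypergeom_two_sided(5, 10, 5, 10) == pytest.approx(1.0)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_two_sided(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_two_sided(0, 4, 8, 10)  # k < max(0, n-(N-K)) = 2

    def test_exhaustive_grid_matches_enumeration(self):
        """Every (N <= 12, K, n, k) agrees with the exact-fraction oracle."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, n - (N - K)), min(n, K) + 1):
                        got = hypergeom_two_sided(k, n, K, N)
                        want = enumeration_p(k, n, K, N)
                        assert got == pytest.approx(want, rel=1e-9), (N, K, n, k)

    def test_smaller_tail_bounded_by_two_sided(self, rng):
        # for a unimodal pmf the observed side's tail is fully included in
        # the minimum-likelihood two-sided sum
        from scipy.stats import hypergeom as hg
        for _ in range(200):
            N = int(rng.integers(2, 40))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            lo, hi = max(0, n - (N - K)), min(n, K)
            k = int(rng.integers(lo, hi + 1))
            rv = hg(N, K, n)
            smaller_tail = min(float(rv.cdf(k)), float(rv.sf(k - 1)))
            assert hypergeom_two_sided(k, n, K, N) >= smaller_tail - 1e-12


class TestPatternEnrichment:
    def test_gene_set_equals_universe_all_p_one(self):
        universe = {f"g{i}" for i in range(20)}
        anno = {"t1": {"g0", "g1"}, "t2": {"g5"}}
        results = pattern_enrichment(universe, anno, universe)
        assert all(r.p_two_sided == pytest.approx(1.0) for r in results)
        assert all(r.k == r.K for r in results)

    def test_planted_term_ranks_first(self, rng):
        universe = [f"g{i}" for i in range(1000)]
        planted = set(universe[:25])
        gene_set = set(universe[:20])  # entire set inside the planted term
        anno = {"planted": planted}
        for t in range(8):
            anno[f"bg{t}"] = set(rng.choice(universe, 50, replace=False))
        results = pattern_enrichment(gene_set, anno, universe)
        assert results[0].term == "planted"
        assert results[0].p_bonferroni < 0.05

    def test_empty_terms_excluded_from_bonferroni(self):
        universe = {f"g{i}" for i in range(10)}
        anno = {"t1": {"g0", "g1", "g2"}, "empty": {"zz"}}  # zz not in universe
        results = pattern_enrichment({"g0", "g1"}, anno, universe)
        assert [r.term for r in results] == ["t1"]
        assert results[0].p_bonferroni == pytest.approx(results[0].p_two_sided)

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            pattern_enrichment({"g0"}, {"t": {"g0"}}, set())
        with pytest.raises(ValueError):
            pattern_enrichment(set(), {"t": {"g0"}}, {"g0"})
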