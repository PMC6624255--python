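"""Regulatory-domain gene assignment and expression-pattern enrichment.

Gene regulatory domains follow the basal-plus-extension rule: a strand-aware
basal window around each TSS (default 5 kb upstream, 1 kb downstream),
extended outward up to a cap (default 1 Mb) or until the nearest neighboring
gene's basal domain, whichever comes first. Extension never truncates a
gene's own basal domain, and basal domains of nearby genes may overlap.

Peaks are assigned to every gene whose extended domain contains the peak
midpoint. Enrichment of annotation terms in a gene set against a universe
uses a two-tailed hypergeometric test (minimum-likelihood definition) with
Bonferroni correction over the number of terms actually tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom

from .intervals import GenomicInterval, PeakSet

DEFAULT_UPSTREAM = 5_000
DEFAULT_DOWNSTREAM = 1_000
DEFAULT_MAX_EXTENSION = 1_000_000


@dataclass(frozen=True)
class GeneModel:
    """A gene reduced to its TSS, strand and expression-pattern terms."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    pattern_terms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if self.tss < 0:
            raise ValueError("tss must be >= 0")


@dataclass(frozen=True)
class RegulatoryDomain:
    """Basal and extended regulatory spans of one gene."""

    gene_id: str
    basal: GenomicInterval
    extended: GenomicInterval

    def __post_init__(self) -> None:
        if not (
            self.extended.start <= self.basal.start
            and self.basal.end <= self.extended.end
        ):
            raise ValueError("basal domain must lie within the extended domain")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one term in a gene set."""

    term: str
    k: int  # term genes in the set
    n: int  # set size
    K: int  # term genes in the universe
    N: int  # universe size
    p_two_sided: float
    p_bonferroni: float

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p_two_sided)


def _basal_span(gene: GeneModel, upstream: int, downstream: int) -> tuple[int, int]:
    if gene.strand == "+":
        lo, hi = gene.tss - upstream, gene.tss + downstream
    else:
        lo, hi = gene.tss - downstream, gene.tss + upstream
    return max(lo, 0), hi


def build_domains(
    genes: Sequence[GeneModel],
    genome: Mapping[str, int] | None = None,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    max_extension: int = DEFAULT_MAX_EXTENSION,
) -> list[RegulatoryDomain]:
    """Basal-plus-extension regulatory domains for a gene list.

    Extension on each side reaches outward from the basal edge until the
    nearer of the extension cap or the nearest neighboring gene's basal
    domain edge; if a neighbor's basal domain already overlaps the gene's
    own, extension on that side is zero. Domains never cross contig ends
    when ``genome`` (contig sizes) is given. Output order follows input.
    """
    by_chrom: dict[str, list[int]] = {}
    for idx, g in enumerate(genes):
        by_chrom.setdefault(g.chrom, []).append(idx)
    spans = [_basal_span(g, upstream, downstream) for g in genes]
    left_stop = [-1] * len(genes)  # -1: unconstrained
    right_stop = [-1] * len(genes)

    for chrom, idxs in by_chrom.items():
        S = np.array([spans[i][0] for i in idxs], dtype=np.int64)
        E = np.array([spans[i][1] for i in idxs], dtype=np.int64)
        # left neighbor edge: max over genes with a strictly smaller basal
        # start of min(their basal end, this basal start)
        order_s = np.argsort(S, kind="stable")
        pref_max_e = np.concatenate(
            ([np.iinfo(np.int64).min], np.maximum.accumulate(E[order_s]))
        )
        s_sorted = S[order_s]
        # right neighbor edge: min over genes with a strictly larger basal
        # end of max(their basal start, this basal end)
        order_e = np.argsort(E, kind="stable")
        suf_min_s = np.concatenate(
            (np.minimum.accumulate(S[order_e][::-1])[::-1], [np.iinfo(np.int64).max])
        )
        e_sorted = E[order_e]
        for local, gi in enumerate(idxs):
            s_i, e_i = int(S[local]), int(E[local])
            t0 = int(np.searchsorted(s_sorted, s_i, side="left"))
            cand = int(pref_max_e[t0])  # max basal end among S_j < S_i
            if cand > np.iinfo(np.int64).min:
                left_stop[gi] = min(cand, s_i)
            u1 = int(np.searchsorted(e_sorted, e_i, side="right"))
            cand = int(suf_min_s[u1])  # min basal start among E_j > E_i
            if cand < np.iinfo(np.int64).max:
                right_stop[gi] = max(cand, e_i)

    domains = []
    for gi, g in enumerate(genes):
        b_lo, b_hi = spans[gi]
        ext_lo = max(b_lo - max_extension, 0)
        if left_stop[gi] >= 0:
            ext_lo = max(ext_lo, left_stop[gi])
        ext_hi = b_hi + max_extension
        if right_stop[gi] >= 0:
            ext_hi = min(ext_hi, right_stop[gi])
        if genome is not None:
            size = genome[g.chrom]
            b_hi = min(b_hi, size)
            ext_hi = min(ext_hi, size)
        ext_lo = min(ext_lo, b_lo)
        ext_hi = max(ext_hi, b_hi)
        domains.append(
            RegulatoryDomain(
                g.gene_id,
                GenomicInterval(g.chrom, b_lo, b_hi, g.strand),
                GenomicInterval(g.chrom, ext_lo, ext_hi, g.strand),
            )
        )
    return domains


def assign_peaks(
    peaks: PeakSet, domains: Sequence[RegulatoryDomain]
) -> tuple[dict[str, list[str]], list[str]]:
    """Map each peak to all genes whose extended domain holds its midpoint.

    Returns (assignments: peak name -> gene ids, unassigned peak names).
    Invariant to peak input order (each peak is handled independently and
    gene lists are sorted).
    """
    by_chrom: dict[str, list[RegulatoryDomain]] = {}
    for d in domains:
        by_chrom.setdefault(d.extended.chrom, []).append(d)
    assignments: dict[str, list[str]] = {}
    unassigned: list[str] = []
    for peak in peaks:
        mid = peak.interval.midpoint
        hits = sorted(
            d.gene_id
            for d in by_chrom.get(peak.chrom, ())
            if d.extended.start <= mid < d.extended.end
        )
        if hits:
            assignments[peak.name] = hits
        else:
            unassigned.append(peak.name)
    return assignments, unassigned


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_two_sided(
    k: int, n: int, K: int, N: int, doubled_tail: bool = False
) -> float:
    """Two-tailed hypergeometric p for k successes in n draws (K of N marked).

    Default is the minimum-likelihood definition: the sum of P(X = x) over
    every outcome x no more probable than the observed k (with a small
    relative tolerance for floating-point ties). ``doubled_tail`` instead
    doubles the smaller one-sided tail, capped at 1.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(n, K) and k >= max(0, n - (N - K))):
        raise ValueError(f"invalid hypergeometric arguments k={k}, n={n}, K={K}, N={N}")
    rv = hypergeom(N, K, n)
    if doubled_tail:
        lower = float(rv.cdf(k))
        upper = float(rv.sf(k - 1))
        return min(1.0, 2.0 * min(lower, upper))
    support = np.arange(max(0, n - (N - K)), min(n, K) + 1)
    pmf = rv.pmf(support)
    p_obs = float(rv.pmf(k))
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    return min(max(p, p_obs), 1.0)


def pattern_enrichment(
    gene_set: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    doubled_tail: bool = False,
) -> list[EnrichmentResult]:
    """Per-term hypergeometric enrichment of a gene set within a universe.

    Terms with no universe genes after intersection are excluded from both
    testing and the Bonferroni denominator. Results are sorted ascending by
    p (ties broken by term label); slice for a top-10 display.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("empty universe")
    genes = set(gene_set) & universe_set
    if not genes:
        raise ValueError("empty gene set (after universe intersection)")
    n, N = len(genes), len(universe_set)
    tested = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & universe_set
        if not term_genes:
            continue
        K = len(term_genes)
        k = len(genes & term_genes)
        p = hypergeom_two_sided(k, n, K, N, doubled_tail=doubled_tail)
        tested.append((term, k, K, p))
    m = len(tested)
    results = [
        EnrichmentResult(term, k, n, K, N, p, min(1.0, p * m))
        for term, k, K, p in tested
    ]
    results.sort(key=lambda r: (r.p_two_sided, r.term))
    return results


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read gene TSS records from BED6 (name = gene id; TSS is the strand-
    aware 5' end of the record)."""
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"line {lineno}: expected BED6")
            start, end, strand = int(f[1]), int(f[2]), f[5]
            tss = start if strand == "+" else end - 1
            genes.append(GeneModel(f[3], f[0], tss, strand))
    return genes


def read_annotation_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column term<TAB>gene annotation table."""
    anno: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {lineno}: expected 'term<TAB>gene'")
            anno.setdefault(parts[0], set()).add(parts[1])
    return anno


def write_enrichment_tsv(results: Sequence[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tk\tn\tK\tN\tp\tp_bonferroni\tneg_log10_p\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.k}\t{r.n}\t{r.K}\t{r.N}\t{r.p_two_sided!r}\t"
                f"{r.p_bonferroni!r}\t{r.neg_log10_p!r}\n"
            )
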