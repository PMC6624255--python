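"""Synthetic inputs with planted ground truth for every pipeline stage.

The generators emulate, at desk scale, the data shapes the pipeline consumes:

* a two-factor / two-timepoint peak landscape with planted transition-group
  labels (including a "pioneered" class: factor-bound at both stages,
  accessible only at the second);
* paired-end-like stranded reads whose inferred Tn5 cut sites carry a planted
  footprint around motif centers — insertion intensity is multiplied by a
  flank enrichment within +/-50 bp of each motif center and by a protection
  factor (< 1) over the central protected zone, so the aggregate profile's
  central-to-flank ratio recovers the protection factor;
* per-experiment read pools with controlled fractions of reads in peaks
  (FRiP) for normalization testing;
* a gene universe with expression-pattern term labels and a planted
  over-represented term in the emitted gene set.

All randomness flows through one ``numpy.random.Generator`` seeded from
``SimConfig.seed``; fixed seed means byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cutsites import ReadRecord, write_fragments_bed
from .footprint import MotifHit, write_motifs_bed
from .intervals import GenomicInterval, Peak, PeakSet, write_narrowpeak
from .regdomains import GeneModel
from .transitions import STATE_ALPHABET

# the 15 ordered state pairs a region can be planted with ("-->-" carries no
# peak at all and cannot exist); 3 of them are factor-free and will be
# dropped by the classifier
ALL_GROUP_LABELS = [
    f"{s1}->{s2}"
    for s1 in STATE_ALPHABET
    for s2 in STATE_ALPHABET
    if not (s1 == "-" and s2 == "-")
]
DROPPED_GROUP_LABELS = [
    lab for lab in ALL_GROUP_LABELS
    if lab.split("->")[0] in ("A", "-") and lab.split("->")[1] in ("A", "-")
]


def _default_group_counts() -> dict[str, int]:
    """500 pioneered + 300 bound-closed-both + 4,200 spread over the rest."""
    counts = {"P->PA": 500, "P->P": 300}
    others = [lab for lab in ALL_GROUP_LABELS if lab not in counts]
    base, extra = divmod(4200, len(others))
    for i, lab in enumerate(others):
        counts[lab] = base + (1 if i < extra else 0)
    return counts


@dataclass
class FootprintParams:
    protection_factor: float = 0.2      # insertion intensity multiplier in the core
    protected_halfwidth: int = 10       # core half-width (20-bp protected zone)
    flank_enrichment: float = 3.0       # intensity multiplier within +/-50 bp
    flank_halfwidth: int = 50

    def __post_init__(self) -> None:
        if not 0 < self.protection_factor <= 1:
            raise ValueError("protection_factor must be in (0, 1]")


@dataclass
class LandscapeParams:
    group_counts: dict[str, int] = field(default_factory=_default_group_counts)
    region_width: int = 400
    min_gap: int = 600
    summit_jitter: int = 20


@dataclass
class ReadParams:
    n_fragments: int = 50_000   # expected cut-site events per experiment
    read_length: int = 50
    long_fragment_fraction: float = 0.01  # > 2 kb tail, removed by the filter


@dataclass
class EnrichmentParams:
    n_terms: int = 10
    planted_term: str = "term_00"
    effect_size: float = 4.0    # sampling weight of planted-term genes; 1 = null
    set_size: int = 50


@dataclass
class SimConfig:
    genome: dict[str, int] = field(default_factory=lambda: {"chrS": 10_000_000})
    n_genes: int = 1_000
    n_motifs: int = 200
    footprint: FootprintParams = field(default_factory=FootprintParams)
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    reads: ReadParams = field(default_factory=ReadParams)
    enrichment: EnrichmentParams = field(default_factory=EnrichmentParams)
    seed: int = 0

    @property
    def main_contig(self) -> str:
        return next(iter(self.genome))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class GroundTruth:
    """Planted truth mirrored by the emitted files."""

    region_labels: list[tuple[str, int, int, str]] = field(default_factory=list)
    footprint: dict = field(default_factory=dict)
    frips: dict[str, float] = field(default_factory=dict)
    planted_term: str = ""
    term_of_gene: dict[str, str] = field(default_factory=dict)
    gene_set: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )


# ---------------------------------------------------------------------------
# Landscape (transition groups)
# ---------------------------------------------------------------------------

def simulate_landscape(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[PeakSet, PeakSet, PeakSet, PeakSet, GroundTruth]:
    """Plant non-overlapping regions with per-group ChIP/ATAC peak patterns.

    Returns (chip_t1, atac_t1, chip_t2, atac_t2, truth). Each region emits a
    peak into the sets its planted state pair dictates; narrowPeak summits
    sit at region centers plus a small jitter.
    """
    rng = rng or cfg.rng()
    lp = cfg.landscape
    unknown = set(lp.group_counts) - set(ALL_GROUP_LABELS)
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    labels = [lab for lab, c in sorted(lp.group_counts.items()) for _ in range(c)]
    n = len(labels)
    contig = cfg.main_contig
    size = cfg.genome[contig]
    slot = size // max(n, 1)
    if n == 0:
        empty = [PeakSet([], label=t) for t in ("chip_t1", "atac_t1", "chip_t2", "atac_t2")]
        return (*empty, GroundTruth())
    if slot < lp.region_width + lp.min_gap:
        required = n * (lp.region_width + lp.min_gap)
        raise ValueError(
            f"genome too small for {n} regions: need >= {required} bases"
        )
    perm = rng.permutation(n)
    shuffled = [labels[i] for i in perm]
    sets: dict[str, list[Peak]] = {
        "chip_t1": [], "atac_t1": [], "chip_t2": [], "atac_t2": []
    }
    truth = GroundTruth()
    for i, lab in enumerate(shuffled):
        start = i * slot + int(rng.integers(0, slot - lp.region_width - lp.min_gap + 1))
        iv = GenomicInterval(contig, start, start + lp.region_width)
        s1, s2 = lab.split("->")
        jitter = int(rng.integers(-lp.summit_jitter, lp.summit_jitter + 1))
        summit = min(max(lp.region_width // 2 + jitter, 0), lp.region_width - 1)
        for stage, state in (("t1", s1), ("t2", s2)):
            if state in ("P", "PA"):
                sets[f"chip_{stage}"].append(
                    Peak(iv, summit, 100.0, f"chip_{stage}_{i}")
                )
            if state in ("A", "PA"):
                sets[f"atac_{stage}"].append(
                    Peak(iv, summit, 100.0, f"atac_{stage}_{i}")
                )
        truth.region_labels.append((contig, iv.start, iv.end, lab))
    return (
        PeakSet(sets["chip_t1"], "chip_t1"),
        PeakSet(sets["atac_t1"], "atac_t1"),
        PeakSet(sets["chip_t2"], "chip_t2"),
        PeakSet(sets["atac_t2"], "atac_t2"),
        truth,
    )


# ---------------------------------------------------------------------------
# Motifs and cut-site reads (footprints)
# ---------------------------------------------------------------------------

def simulate_motifs(
    cfg: SimConfig, rng: np.random.Generator | None = None, width: int = 10,
    spacing: int = 1_000, margin: int = 5_000,
) -> list[MotifHit]:
    """Evenly slotted motif hits (random in-slot offset and strand)."""
    rng = rng or cfg.rng()
    contig = cfg.main_contig
    size = cfg.genome[contig]
    usable = size - 2 * margin
    slot = usable // cfg.n_motifs
    if slot < spacing:
        raise ValueError("genome too small for requested motif count/spacing")
    hits = []
    for i in range(cfg.n_motifs):
        start = margin + i * slot + int(rng.integers(0, slot - width))
        strand = "+" if rng.random() < 0.5 else "-"
        hits.append(
            MotifHit(GenomicInterval(contig, start, start + width, strand),
                     motif_id=f"motif_{i}", score=1.0)
        )
    return hits


def _fragment_lengths(rng: np.random.Generator, n: int, rp: ReadParams) -> np.ndarray:
    """ATAC-like mixture: sub-nucleosomal + mono-nucleosomal + a long tail."""
    comp = rng.random(n)
    out = np.empty(n, dtype=np.int64)
    sub = comp < 0.60
    mono = (comp >= 0.60) & (comp < 1.0 - rp.long_fragment_fraction)
    long_ = comp >= 1.0 - rp.long_fragment_fraction
    out[sub] = np.clip(rng.normal(80, 25, sub.sum()), 35, None).astype(np.int64)
    out[mono] = np.clip(rng.normal(190, 35, mono.sum()), 120, None).astype(np.int64)
    out[long_] = rng.integers(2_050, 4_000, long_.sum())
    return out


def simulate_cutsites(
    cfg: SimConfig,
    motifs: list[MotifHit],
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], GroundTruth]:
    """Stranded reads whose cut sites carry the planted footprint.

    Insertion intensity is uniform background, multiplied by
    ``flank_enrichment`` within the flank half-width of each motif center and
    additionally by ``protection_factor`` within the protected core. Each
    insertion emits one read on a random strand positioned so that the
    +5/-4 cut-site rule recovers the insertion base exactly.
    """
    rng = rng or cfg.rng()
    fp = cfg.footprint
    rp = cfg.reads
    contig = cfg.main_contig
    size = cfg.genome[contig]
    mult = np.ones(size, dtype=np.float32)
    for hit in motifs:
        c = (hit.interval.start + hit.interval.end - 1) // 2
        lo, hi = max(c - fp.flank_halfwidth, 0), min(c + fp.flank_halfwidth + 1, size)
        mult[lo:hi] *= fp.flank_enrichment
        plo, phi = max(c - fp.protected_halfwidth, 0), min(c + fp.protected_halfwidth + 1, size)
        mult[plo:phi] *= fp.protection_factor
    background = rp.n_fragments / float(mult.sum(dtype=np.float64))
    counts = rng.poisson(lam=mult.astype(np.float64) * background)
    positions = np.repeat(np.flatnonzero(counts), counts[counts > 0])
    margin = rp.read_length + 10
    positions = np.clip(positions, margin, size - margin)
    n = len(positions)
    strands = rng.random(n) < 0.5
    frags = _fragment_lengths(rng, n, rp)
    reads = []
    for pos, plus, frag in zip(positions, strands, frags):
        pos = int(pos)
        if plus:
            start = pos - 5
            reads.append(ReadRecord(contig, start, start + rp.read_length, "+", int(frag)))
        else:
            end = pos + 5  # 5' base end-1 = pos+4; cut = (pos+4) - 4 = pos
            reads.append(ReadRecord(contig, end - rp.read_length, end, "-", int(frag)))
    truth = GroundTruth(
        footprint={
            "protection_factor": fp.protection_factor,
            "protected_halfwidth": fp.protected_halfwidth,
            "flank_enrichment": fp.flank_enrichment,
            "flank_halfwidth": fp.flank_halfwidth,
            "n_events": n,
        }
    )
    return reads, truth


# ---------------------------------------------------------------------------
# RiP-normalization experiments
# ---------------------------------------------------------------------------

def simulate_rip_experiments(
    cfg: SimConfig,
    frips: dict[str, float],
    n_reads: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[ReadRecord]], PeakSet, GroundTruth]:
    """Per-experiment read pools with controlled FRiP over a shared atlas.

    The atlas is a fixed comb of disjoint peaks; each read lands fully inside
    a random peak with probability frip, else fully outside (with a safety
    margin), so the realized reads-in-peaks count is Binomial(n_reads, frip).
    """
    rng = rng or cfg.rng()
    n_reads = n_reads or cfg.reads.n_fragments
    rl = cfg.reads.read_length
    contig = cfg.main_contig
    size = cfg.genome[contig]
    n_peaks, pw, gap = 20, 5_000, 20_000
    span = n_peaks * (pw + gap)
    if span + gap >= size:
        raise ValueError("genome too small for the RiP peak comb")
    peaks = [
        Peak(GenomicInterval(contig, s, s + pw), pw // 2, 100.0, f"rip_peak_{i}")
        for i, s in enumerate(range(gap, gap + span, pw + gap))
    ]
    atlas = PeakSet(peaks, label="rip_atlas")
    bg_lo, bg_hi = gap + span + 2_000, size - rl - 1
    experiments: dict[str, list[ReadRecord]] = {}
    truth = GroundTruth(frips=dict(frips))
    for label in sorted(frips):
        f = frips[label]
        inside = rng.random(n_reads) < f
        peak_idx = rng.integers(0, n_peaks, n_reads)
        in_off = rng.integers(0, pw - rl, n_reads)
        out_pos = rng.integers(bg_lo, bg_hi - rl, n_reads)
        reads = []
        for i in range(n_reads):
            if inside[i]:
                s = peaks[int(peak_idx[i])].start + int(in_off[i])
            else:
                s = int(out_pos[i])
            strand = "+" if rng.random() < 0.5 else "-"
            reads.append(ReadRecord(contig, s, s + rl, strand, 200))
        experiments[label] = reads
    return experiments, atlas, truth


# ---------------------------------------------------------------------------
# Gene annotation / enrichment
# ---------------------------------------------------------------------------

def simulate_annotation(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GeneModel], dict[str, set[str]], set[str], GroundTruth]:
    """Gene universe with pattern terms and a planted-enriched gene set.

    Each gene carries one term (uniform multinomial). The emitted gene set is
    drawn without replacement with sampling weight ``effect_size`` for genes
    of the planted term and 1 otherwise; effect 1 is the null.
    """
    rng = rng or cfg.rng()
    ep = cfg.enrichment
    if ep.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    contig = cfg.main_contig
    size = cfg.genome[contig]
    spacing = size // (cfg.n_genes + 1)
    genes = []
    term_ids = [f"term_{i:02d}" for i in range(ep.n_terms)]
    if ep.planted_term not in term_ids:
        raise ValueError(f"planted_term {ep.planted_term!r} not among generated terms")
    assign = rng.integers(0, ep.n_terms, cfg.n_genes)
    annotation: dict[str, set[str]] = {t: set() for t in term_ids}
    truth = GroundTruth(planted_term=ep.planted_term)
    for i in range(cfg.n_genes):
        gid = f"gene_{i:04d}"
        tss = (i + 1) * spacing + int(rng.integers(-spacing // 4, spacing // 4 + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        term = term_ids[int(assign[i])]
        genes.append(GeneModel(gid, contig, max(tss, 0), strand, frozenset({term})))
        annotation[term].add(gid)
        truth.term_of_gene[gid] = term
    weights = np.where(assign == term_ids.index(ep.planted_term), ep.effect_size, 1.0)
    weights /= weights.sum()
    chosen = rng.choice(cfg.n_genes, size=ep.set_size, replace=False, p=weights)
    gene_set = {f"gene_{i:04d}" for i in chosen}
    truth.gene_set = sorted(gene_set)
    return genes, annotation, gene_set, truth


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------

def simulate_to_dir(cfg: SimConfig, outdir: str | Path) -> dict[str, Path]:
    """Run all generators and write their outputs as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = cfg.rng()
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = out / "chrom.sizes"
    with open(paths["chrom_sizes"], "w") as fh:
        for chrom, size in cfg.genome.items():
            fh.write(f"{chrom}\t{size}\n")

    chip1, atac1, chip2, atac2, truth_land = simulate_landscape(cfg, rng)
    for name, ps in (("chip_t1", chip1), ("atac_t1", atac1),
                     ("chip_t2", chip2), ("atac_t2", atac2)):
        paths[name] = out / f"{name}.narrowPeak"
        write_narrowpeak(ps, paths[name])

    motifs = simulate_motifs(cfg, rng)
    paths["motifs"] = out / "motifs.bed"
    write_motifs_bed(motifs, paths["motifs"])

    reads, truth_fp = simulate_cutsites(cfg, motifs, rng)
    paths["fragments"] = out / "fragments.bed"
    write_fragments_bed(reads, paths["fragments"])

    genes, annotation, gene_set, truth_anno = simulate_annotation(cfg, rng)
    paths["genes"] = out / "genes.bed"
    with open(paths["genes"], "w") as fh:
        for g in genes:
            start = g.tss if g.strand == "+" else g.tss  # single-base record
            fh.write(f"{g.chrom}\t{start}\t{start + 1}\t{g.gene_id}\t0\t{g.strand}\n")
    paths["annotation"] = out / "annotation.tsv"
    with open(paths["annotation"], "w") as fh:
        for term in sorted(annotation):
            for gid in sorted(annotation[term]):
                fh.write(f"{term}\t{gid}\n")
    paths["gene_set"] = out / "gene_set.txt"
    Path(paths["gene_set"]).write_text("\n".join(sorted(gene_set)) + "\n")

    truth = GroundTruth(
        region_labels=truth_land.region_labels,
        footprint=truth_fp.footprint,
        planted_term=truth_anno.planted_term,
        term_of_gene=truth_anno.term_of_gene,
        gene_set=truth_anno.gene_set,
    )
    paths["ground_truth"] = out / "ground_truth.json"
    truth.to_json(paths["ground_truth"])
    return paths
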