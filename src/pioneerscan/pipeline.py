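"""End-to-end orchestration: simulate -> cutsites -> normalization ->
footprint/distances -> clustering -> transitions -> enrichment.

A single :class:`RunConfig` carries every fixed constant of the analysis
(cut-site offsets are not configurable — they are the method's definition —
but windows, the fragment cap, regulatory-domain parameters and k are), so
any deviation from the defaults is visible in the machine-readable run
report. Defaults: 100-bp footprint window, 400-bp summit-distance window,
5-bp cut-site extension, 2,000-bp fragment cap, regulatory domains of
5 kb upstream / 1 kb downstream / 1 Mb maximum extension.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .clustering import kmeans_cluster
from .cutsites import build_cutsite_track
from .footprint import footprint_profile, protection_ratio, summit_motif_distances
from .intervals import GenomicInterval, Peak, PeakSet
from .regdomains import build_domains, pattern_enrichment
from .ripnorm import count_reads_in_peaks, execute_plan, plan_subsampling
from .simulate import (SimConfig, simulate_annotation, simulate_cutsites,
                       simulate_landscape, simulate_motifs,
                       simulate_rip_experiments)
from .transitions import build_regions, classify_transitions, group_sizes

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


@dataclass
class RunConfig:
    """All pipeline constants, overridable from YAML."""

    seed: int = 0
    outdir: str = "pioneerscan_run"
    # stage parameters (defaults are the analysis constants)
    footprint_window: int = 100
    distance_window: int = 400
    extension: int = 5
    max_fragment: int = 2_000
    great_upstream: int = 5_000
    great_downstream: int = 1_000
    great_max_extension: int = 1_000_000
    kmeans_k: int = 4
    cluster_rows: int = 2_000
    rip_frips: dict = field(default_factory=lambda: {
        "exp_a": 0.1, "exp_b": 0.2, "exp_c": 0.3, "exp_d": 0.4
    })
    rip_reads: int = 50_000
    enrichment_top: int = 10
    # nested synthetic-data overrides (SimConfig field names)
    simulate: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        sim = raw.get("simulate", {})
        sim_known = {f.name for f in dataclasses.fields(SimConfig)}
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ConfigError(f"unknown simulate keys: {sorted(sim_unknown)}")
        return cls(**raw)

    def sim_config(self) -> SimConfig:
        from .simulate import (EnrichmentParams, FootprintParams,
                               LandscapeParams, ReadParams)

        nested = {
            "footprint": FootprintParams,
            "landscape": LandscapeParams,
            "reads": ReadParams,
            "enrichment": EnrichmentParams,
        }
        kwargs = dict(self.simulate)
        for key, cls in nested.items():
            if isinstance(kwargs.get(key), dict):
                kwargs[key] = cls(**kwargs[key])
        kwargs.setdefault("seed", self.seed)
        return SimConfig(**kwargs)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run(config: RunConfig) -> dict:
    """Execute all stages on synthetic inputs; return the run report.

    The report is also written to ``<outdir>/report.json``. Any stage
    failure raises :class:`StageError` naming the stage.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config.sim_config()
    rng = np.random.default_rng(config.seed)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            try:
                logger.info("stage %s", name)
                report["stages"][name] = fn()
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return deco

    @stage("transitions")
    def _():
        chip1, atac1, chip2, atac2, truth = simulate_landscape(cfg, rng)
        records = classify_transitions(build_regions(chip1, atac1, chip2, atac2))
        sizes = group_sizes(records)
        planted = {}
        for _, _, _, lab in truth.region_labels:
            planted[lab] = planted.get(lab, 0) + 1
        return {
            "group_sizes": sizes,
            "planted_sizes": dict(sorted(planted.items())),
            "n_regions": len(truth.region_labels),
            "n_classified": len(records),
            "n_pioneered": sizes.get("P->PA", 0),
        }

    @stage("footprint")
    def _():
        motifs = simulate_motifs(cfg, rng)
        reads, truth = simulate_cutsites(cfg, motifs, rng)
        track = build_cutsite_track(
            reads, cfg.genome, max_fragment=config.max_fragment,
            extension=config.extension,
        )
        profile = footprint_profile(track, motifs, window=config.footprint_window)
        # protection factor from unsmoothed events (calibrated Poisson SE)
        event_track = build_cutsite_track(
            reads, cfg.genome, max_fragment=config.max_fragment, extension=0
        )
        ratio, se = protection_ratio(
            footprint_profile(event_track, motifs, window=config.footprint_window)
        )
        # summit-distance control: ChIP-like peaks whose summits sit on motifs
        peaks = []
        contig_size = cfg.genome[cfg.main_contig]
        for i, m in enumerate(motifs):
            c = (m.interval.start + m.interval.end - 1) // 2
            lo = max(c - 200, 0)
            hi = min(c + 200, contig_size)
            jitter = int(rng.integers(-25, 26))
            summit = min(max(c + jitter - lo, 0), hi - lo - 1)
            peaks.append(Peak(GenomicInterval(m.interval.chrom, lo, hi),
                              summit, 100.0, f"fp_peak_{i}"))
        dist = summit_motif_distances(PeakSet(peaks, "fp_peaks"), motifs,
                                      window=config.distance_window)
        mean_abs = (
            float((np.abs(dist.distances) * dist.counts).sum() / dist.counts.sum())
            if dist.n_pairs else float("nan")
        )
        profile.to_tsv(out / "footprint_profile.tsv")
        dist.to_tsv(out / "summit_distances.tsv")
        return {
            "n_sites": profile.n_sites,
            "n_events": track.total_events,
            "protection_ratio": ratio,
            "protection_ratio_se": se,
            "planted_protection_factor": truth.footprint["protection_factor"],
            "distance_pairs": dist.n_pairs,
            "mean_abs_summit_distance": mean_abs,
        }

    @stage("rip_normalization")
    def _():
        experiments, atlas, truth = simulate_rip_experiments(
            cfg, config.rip_frips, config.rip_reads, rng
        )
        counts = [
            count_reads_in_peaks(reads, atlas, label)
            for label, reads in sorted(experiments.items())
        ]
        plan = plan_subsampling(counts, seed=config.seed)
        subsampled = execute_plan(experiments, plan)
        post = {
            label: count_reads_in_peaks(reads, atlas, label).reads_in_peaks
            for label, reads in subsampled.items()
        }
        plan.to_json(out / "rip_plan.json", counts)
        ref_rip = next(
            c.reads_in_peaks for c in counts if c.label == plan.reference_label
        )
        return {
            "reference": plan.reference_label,
            "targets": plan.targets,
            "pre_rip": {c.label: c.reads_in_peaks for c in counts},
            "post_rip": post,
            "reference_rip": ref_rip,
            "max_z": max(
                abs(v - ref_rip) / np.sqrt(ref_rip) for v in post.values()
            ),
        }

    @stage("clustering")
    def _():
        # planted early-vs-late two-block matrix (high-t1/low-t2 vs converse)
        n = config.cluster_rows
        half = n // 2
        block = rng.normal(0, 1, size=(n, 20))
        block[:half, :10] += 8.0
        block[half:, 10:] += 8.0
        truth_labels = np.array([0] * half + [1] * (n - half))
        assign = kmeans_cluster(block, k=2, seed=config.seed)
        agree = max(
            float((assign.labels == truth_labels).mean()),
            float((assign.labels == 1 - truth_labels).mean()),
        )
        return {
            "k": 2,
            "sizes": {str(lab): n for lab, n in assign.sizes().items()},
            "label_agreement": agree,
            "inertia": assign.inertia,
            "n_iter": len(assign.inertia_history),
        }

    @stage("enrichment")
    def _():
        genes, annotation, gene_set, truth = simulate_annotation(cfg, rng)
        domains = build_domains(
            genes, cfg.genome, config.great_upstream,
            config.great_downstream, config.great_max_extension,
        )
        results = pattern_enrichment(gene_set, annotation,
                                     {g.gene_id for g in genes})
        top = results[: config.enrichment_top]
        return {
            "planted_term": truth.planted_term,
            "n_domains": len(domains),
            "top_terms": [
                {
                    "term": r.term, "k": r.k, "K": r.K,
                    "p": r.p_two_sided, "p_bonferroni": r.p_bonferroni,
                    "neg_log10_p": r.neg_log10_p,
                }
                for r in top
            ],
            "planted_rank": 1 + [r.term for r in results].index(truth.planted_term),
        }

    report["digests"] = {
        p.name: _digest(p) for p in sorted(out.glob("*")) if p.is_file()
    }
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report
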