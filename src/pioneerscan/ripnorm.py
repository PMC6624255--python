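"""Cross-experiment normalization by reads falling into peaks (RiP).

Library size alone is a poor scaling basis for ATAC/ChIP experiments with
different signal-to-background ratios. Instead, per-experiment reads are
counted inside a shared merged-peak atlas; the experiment with the fewest
reads-in-peaks is the reference, and every other experiment is randomly
subsampled to the total-read count expected to leave it with the reference's
reads-in-peaks: target_total_i = round(RiP_ref / FRiP_i).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .cutsites import ReadRecord
from .intervals import PeakSet, _OverlapIndex, GenomicInterval


@dataclass(frozen=True)
class ExperimentCounts:
    """Per-experiment totals: library size, reads in peaks, their ratio."""

    label: str
    total_reads: int
    reads_in_peaks: int

    def __post_init__(self) -> None:
        if not 0 <= self.reads_in_peaks <= self.total_reads:
            raise ValueError("reads_in_peaks must lie in [0, total_reads]")

    @property
    def frip(self) -> float:
        return self.reads_in_peaks / self.total_reads if self.total_reads else 0.0


@dataclass
class SubsamplePlan:
    """Per-experiment target library sizes for RiP equalization."""

    targets: dict[str, int]
    reference_label: str
    seed: int

    def to_json(self, path: str | Path, counts: Sequence[ExperimentCounts] | None = None) -> None:
        payload: dict = {
            "reference": self.reference_label,
            "seed": self.seed,
            "targets": self.targets,
        }
        if counts is not None:
            payload["experiments"] = [
                {
                    "label": c.label,
                    "total": c.total_reads,
                    "rip": c.reads_in_peaks,
                    "frip": c.frip,
                    "target": self.targets[c.label],
                }
                for c in counts
            ]
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def count_reads_in_peaks(
    reads: Sequence[ReadRecord], merged_peaks: PeakSet, label: str = ""
) -> ExperimentCounts:
    """Count reads overlapping (>= 1 bp) any merged peak; each read once."""
    index = _OverlapIndex(merged_peaks.intervals())
    n_in = sum(
        1
        for r in reads
        if index.any_overlap(GenomicInterval(r.chrom, r.start, r.end, "."))
    )
    return ExperimentCounts(label=label, total_reads=len(reads), reads_in_peaks=n_in)


def plan_subsampling(
    counts: Sequence[ExperimentCounts], seed: int = 0
) -> SubsamplePlan:
    """Choose the min-RiP experiment as reference and size the others.

    target_total_i = round(RiP_ref / FRiP_i), clamped to the pool size; the
    reference keeps its own total. The plan is invariant to input order
    (ties on RiP break deterministically by label).
    """
    if len(counts) < 2:
        raise ValueError("need >= 2 experiments to normalize")
    for c in counts:
        if c.frip == 0:
            raise ValueError(f"experiment {c.label!r} has FRiP 0; normalization undefined")
    ref = min(counts, key=lambda c: (c.reads_in_peaks, c.label))
    targets: dict[str, int] = {}
    for c in counts:
        if c.label == ref.label:
            targets[c.label] = c.total_reads
        else:
            targets[c.label] = min(
                int(round(ref.reads_in_peaks / c.frip)), c.total_reads
            )
    return SubsamplePlan(targets=targets, reference_label=ref.label, seed=seed)


def subsample_reads(
    reads: Sequence[ReadRecord], target_total: int, seed: int
) -> list[ReadRecord]:
    """Uniform sample of exactly ``target_total`` reads without replacement.

    Reproducible from ``seed``; sampled reads are returned in their original
    input order.
    """
    if target_total > len(reads):
        raise ValueError(
            f"target {target_total} exceeds pool of {len(reads)} reads"
        )
    if target_total == len(reads):
        return list(reads)
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(len(reads), size=target_total, replace=False))
    return [reads[i] for i in idx]


def execute_plan(
    experiments: dict[str, Sequence[ReadRecord]], plan: SubsamplePlan
) -> dict[str, list[ReadRecord]]:
    """Apply a subsampling plan to per-experiment read pools.

    Each experiment gets an independent stream derived from the plan seed and
    its label, so results do not depend on dict iteration order.
    """
    out: dict[str, list[ReadRecord]] = {}
    for label in sorted(experiments):
        # stable per-experiment sub-seed below 2**31
        sub = (hash_label(label) ^ plan.seed) % (2**31 - 1)
        out[label] = subsample_reads(experiments[label], plan.targets[label], sub)
    return out


def hash_label(label: str) -> int:
    """Deterministic (process-independent) small hash of a label."""
    h = 2166136261
    for ch in label.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h
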