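"""Joint ChIP/ATAC peak-state classification across two timepoints.

A union atlas of regions is built by merging the four input peak sets
(ChIP and ATAC at each of two stages). Each region's state per stage is one
of P (ChIP only), A (ATAC only), PA (both) or "-" (neither), from >= 1 bp
overlap with the corresponding peak set. Regions never bound by the ChIP
factor at either stage are dropped. The ordered state pair is the group
label; two groups carry named aliases:

* ``pioneered`` (P -> PA): bound in closed chromatin at t1, bound and
  accessible at t2 — the signature of pioneer-factor activity.
* ``bound_closed_both`` (P -> P): bound at both stages without a called
  accessibility peak at either.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .clustering import build_matrix
from .cutsites import CutSiteTrack
from .intervals import GenomicInterval, Peak, PeakSet, _OverlapIndex, merge_peaksets

STATE_ALPHABET = ("P", "A", "PA", "-")

GROUP_ALIASES = {
    "P->PA": "pioneered",
    "P->P": "bound_closed_both",
}


@dataclass(frozen=True)
class StateCall:
    """Per-region binary assay states at the two timepoints."""

    region: GenomicInterval
    chip_t1: bool
    atac_t1: bool
    chip_t2: bool
    atac_t2: bool

    def __post_init__(self) -> None:
        if not (self.chip_t1 or self.atac_t1 or self.chip_t2 or self.atac_t2):
            raise ValueError("region carries no peak in any assay/stage")


@dataclass(frozen=True)
class TransitionRecord:
    """A region's ordered state pair and derived group label."""

    region: GenomicInterval
    state_t1: str
    state_t2: str
    group_label: str
    alias: str | None = None


def _pair_state(chip: bool, atac: bool) -> str:
    if chip and atac:
        return "PA"
    if chip:
        return "P"
    if atac:
        return "A"
    return "-"


def build_regions(
    chip_t1: PeakSet, atac_t1: PeakSet, chip_t2: PeakSet, atac_t2: PeakSet
) -> list[StateCall]:
    """Merge the four peak sets into a union atlas and call per-assay states.

    Each merged region's four booleans record >= 1 bp overlap with the
    corresponding input set. Deterministic: regions are in (chrom, start)
    order.
    """
    sets = (chip_t1, atac_t1, chip_t2, atac_t2)
    if all(len(s) == 0 for s in sets):
        raise ValueError("all four peak sets are empty")
    atlas = merge_peaksets(list(sets), label="atlas")
    indexes = [_OverlapIndex(s.intervals()) for s in sets]
    calls = []
    for peak in atlas:
        flags = [idx.any_overlap(peak.interval) for idx in indexes]
        calls.append(StateCall(peak.interval, *flags))
    return calls


def classify_transitions(calls: Sequence[StateCall]) -> list[TransitionRecord]:
    """Label each region by its ordered state pair; drop ChIP-free regions.

    Regions with no ChIP peak at either stage are removed (they carry no
    information about the factor under study). Every surviving region gets
    exactly one group label.
    """
    records = []
    for call in calls:
        if not (call.chip_t1 or call.chip_t2):
            continue
        s1 = _pair_state(call.chip_t1, call.atac_t1)
        s2 = _pair_state(call.chip_t2, call.atac_t2)
        label = f"{s1}->{s2}"
        records.append(
            TransitionRecord(call.region, s1, s2, label, GROUP_ALIASES.get(label))
        )
    return records


def group_sizes(records: Sequence[TransitionRecord]) -> dict[str, int]:
    """Region count per group label, sorted by label."""
    out: dict[str, int] = {}
    for r in records:
        out[r.group_label] = out.get(r.group_label, 0) + 1
    return dict(sorted(out.items()))


def select_group(
    records: Sequence[TransitionRecord], group: str
) -> list[TransitionRecord]:
    """Records in a group, addressed by label ("P->PA") or alias ("pioneered")."""
    hits = [r for r in records if group in (r.group_label, r.alias)]
    if not hits:
        raise ValueError(f"group {group!r} is empty or unknown")
    return hits


def compare_groups_signal(
    track_a: CutSiteTrack,
    track_b: CutSiteTrack,
    records: Sequence[TransitionRecord],
    group: str,
    flank: int = 500,
    bins: int = 50,
) -> dict[str, np.ndarray]:
    """Mean binned profiles of two tracks over one transition group.

    Returns per-bin mean profiles for both tracks over the group's regions
    (anchored at region centers) and their difference (a - b). Tracks are
    expected to be RiP-normalized upstream.
    """
    members = select_group(records, group)
    regions = PeakSet(
        [
            Peak(r.region, r.region.length // 2, 0.0, f"{group}_{i}")
            for i, r in enumerate(members)
        ],
        label=group,
    )
    mat = build_matrix([track_a, track_b], regions, flank=flank, bins=bins,
                       anchor="center", track_labels=["a", "b"])
    prof_a = mat.values[:, :bins].mean(axis=0)
    prof_b = mat.values[:, bins:].mean(axis=0)
    return {"a": prof_a, "b": prof_b, "difference": prof_a - prof_b,
            "n_regions": np.array([len(members)])}


def write_groups_bed(records: Sequence[TransitionRecord], path: str | Path) -> None:
    """BED6 export with the group label (alias when defined) as the name."""
    with open(path, "w") as fh:
        for r in records:
            name = r.alias or r.group_label
            fh.write(
                f"{r.region.chrom}\t{r.region.start}\t{r.region.end}\t{name}\t0\t.\n"
            )
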