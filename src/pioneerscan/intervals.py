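"""Genomic interval data model, BED-family I/O and set algebra.

All coordinates are 0-based half-open (BED convention); 1-based inputs must be
converted at the reader boundary. Overlap between two intervals requires at
least one shared base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span [start, end) on a contig."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand: {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 base on the same contig."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Peak:
    """A called peak: an interval plus summit offset, score and name.

    ``summit_offset`` is the 0-based offset of the summit base from ``start``.
    """

    interval: GenomicInterval
    summit_offset: int
    score: float = 0.0
    name: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.summit_offset < self.interval.length:
            raise ValueError(
                f"summit_offset {self.summit_offset} outside peak of length "
                f"{self.interval.length}"
            )
        if self.score < 0:
            raise ValueError("score must be non-negative")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def start(self) -> int:
        return self.interval.start

    @property
    def end(self) -> int:
        return self.interval.end

    @property
    def summit(self) -> int:
        """Absolute genomic position of the summit base."""
        return self.interval.start + self.summit_offset


@dataclass
class PeakSet:
    """An ordered collection of peaks with an experiment/stage label."""

    peaks: list[Peak] = field(default_factory=list)
    label: str = ""

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[Peak]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def sorted(self) -> "PeakSet":
        return PeakSet(
            sorted(self.peaks, key=lambda p: (p.chrom, p.start, p.end)),
            label=self.label,
        )

    def intervals(self) -> list[GenomicInterval]:
        return [p.interval for p in self.peaks]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_peak_line(fields: Sequence[str], lineno: int) -> Peak:
    if len(fields) < 3:
        raise ValueError(f"line {lineno}: expected >= 3 columns, got {len(fields)}")
    try:
        chrom = fields[0]
        start = int(fields[1])
        end = int(fields[2])
        name = fields[3] if len(fields) > 3 else "."
        score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
        strand = fields[5] if len(fields) > 5 else "."
        summit = int(fields[9]) if len(fields) > 9 else -1
    except (ValueError, IndexError) as exc:
        raise ValueError(f"line {lineno}: malformed record ({exc})") from exc
    if start < 0 or end < 0:
        raise ValueError(f"line {lineno}: negative coordinate")
    if summit < 0:
        summit = (end - start) // 2  # midpoint fallback
    try:
        return Peak(GenomicInterval(chrom, start, end, strand), summit, score, name)
    except ValueError as exc:
        raise ValueError(f"line {lineno}: {exc}") from exc


def read_narrowpeak(path: str | Path, label: str = "") -> PeakSet:
    """Read an ENCODE narrowPeak (or >= 3-column BED) file into a PeakSet.

    Column 10, when present and non-negative, is the summit offset from the
    peak start; otherwise the peak midpoint is used. Column 5 is the score.
    """
    peaks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            peaks.append(_parse_peak_line(line.split("\t"), lineno))
    return PeakSet(peaks, label=label or Path(path).stem)


def write_narrowpeak(peakset: PeakSet, path: str | Path) -> None:
    """Write a PeakSet as 10-column narrowPeak (field-lossless round trip)."""
    with open(path, "w") as fh:
        for p in peakset:
            fh.write(
                "\t".join(
                    [
                        p.chrom,
                        str(p.start),
                        str(p.end),
                        p.name,
                        repr(p.score),
                        p.interval.strand,
                        "0",
                        "-1",
                        "-1",
                        str(p.summit_offset),
                    ]
                )
                + "\n"
            )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 records as GenomicIntervals."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"line {lineno}: expected >= 3 columns")
            strand = f[5] if len(f) > 5 else "."
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def clip_to_genome(peakset: PeakSet, genome: dict[str, int]) -> PeakSet:
    """Clip peaks extending past contig ends; warn rather than reject."""
    clipped = []
    for p in peakset:
        size = genome.get(p.chrom)
        if size is None:
            raise ValueError(f"peak on unknown contig {p.chrom}")
        if p.end > size:
            logger.warning("clipping peak %s:%d-%d to contig end %d",
                           p.chrom, p.start, p.end, size)
            new_iv = GenomicInterval(p.chrom, p.start, size, p.interval.strand)
            summit = min(p.summit_offset, new_iv.length - 1)
            clipped.append(Peak(new_iv, summit, p.score, p.name))
        else:
            clipped.append(p)
    return PeakSet(clipped, label=peakset.label)


# ---------------------------------------------------------------------------
# Set algebra
# ---------------------------------------------------------------------------

class _OverlapIndex:
    """Sorted-array overlap queries against a fixed interval collection."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._starts: dict[str, np.ndarray] = {}
        self._maxend: dict[str, np.ndarray] = {}
        for chrom, spans in by_chrom.items():
            spans.sort()
            starts = np.array([s for s, _ in spans], dtype=np.int64)
            ends = np.array([e for _, e in spans], dtype=np.int64)
            self._starts[chrom] = starts
            # prefix running max of ends: any interval i <= j has end <= maxend[j]
            self._maxend[chrom] = np.maximum.accumulate(ends)

    def any_overlap(self, iv: GenomicInterval) -> bool:
        starts = self._starts.get(iv.chrom)
        if starts is None:
            return False
        # candidates start before iv.end; overlap iff the running max end
        # among them exceeds iv.start
        j = int(np.searchsorted(starts, iv.end, side="left")) - 1
        return j >= 0 and int(self._maxend[iv.chrom][j]) > iv.start


def overlap_partition(a: PeakSet, b: PeakSet) -> tuple[PeakSet, PeakSet, PeakSet]:
    """Venn-partition two peak sets by >= 1 bp overlap.

    Returns ``(a_only, b_only, common)``; ``common`` holds the overlapping
    peaks of *both* inputs (a's first, then b's). Counts are conserved:
    ``|a| == |a_only| + |common peaks from a|`` and symmetrically for b.
    """
    idx_b = _OverlapIndex(a_iv := b.intervals())
    idx_a = _OverlapIndex(a.intervals())
    a_only, b_only, common = [], [], []
    for p in a:
        (common if idx_b.any_overlap(p.interval) else a_only).append(p)
    for p in b:
        (common if idx_a.any_overlap(p.interval) else b_only).append(p)
    return (
        PeakSet(a_only, label=f"{a.label}_only"),
        PeakSet(b_only, label=f"{b.label}_only"),
        PeakSet(common, label="common"),
    )


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping intervals into maximal spans, sorted by position."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:  # strict: touching intervals stay separate (half-open)
                cur_e = max(cur_e, e)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(GenomicInterval(chrom, cur_s, cur_e))
    return merged


def merge_peaksets(sets: Sequence[PeakSet], label: str = "merged") -> PeakSet:
    """Merge >= 1 peak sets into one set of maximal non-overlapping spans.

    Merged peaks carry midpoint summits and zero scores (summit identity is
    not meaningful after merging).
    """
    if not sets:
        raise ValueError("merge_peaksets requires at least one PeakSet")
    all_iv = [iv for ps in sets for iv in ps.intervals()]
    if not all_iv:
        return PeakSet([], label=label)
    merged = merge_intervals(all_iv)
    peaks = [
        Peak(iv, iv.length // 2, 0.0, f"{label}_{i}")
        for i, iv in enumerate(merged)
    ]
    return PeakSet(peaks, label=label)
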