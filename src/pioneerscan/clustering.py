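"""Binned signal matrices over regions and k-means partitioning.

Regions (peaks) are expanded to a fixed window around an anchor (summit or
interval center); per-bin mean signal for one or more tracks forms a row per
region. Rows are partitioned by k-means (k-means++ initialization, Lloyd
iterations) with an explicit seed; clusters are reported in decreasing
mean-signal order so labels are stable and comparable across runs.

The Lloyd loop is implemented here (rather than delegated wholesale) so the
per-iteration within-cluster sum of squares is available; the objective must
be non-increasing, which is asserted in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import kmeans_plusplus

from .cutsites import CutSiteTrack
from .intervals import PeakSet


@dataclass
class SignalMatrix:
    """regions x (tracks * bins) matrix of mean binned signal."""

    regions: PeakSet
    bins: int
    flank: int
    values: np.ndarray
    track_labels: list[str]
    clipped: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))

    def to_tsv(self, path: str | Path) -> None:
        header = ["region"] + [
            f"{t}_bin{b}" for t in self.track_labels for b in range(self.bins)
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(header) + "\n")
            for peak, row in zip(self.regions, self.values):
                fh.write(peak.name + "\t" + "\t".join(repr(v) for v in row) + "\n")


@dataclass
class ClusterAssignment:
    """k-means result: per-region labels, centroids and the objective trace."""

    labels: np.ndarray
    k: int
    centroids: np.ndarray
    seed: int
    inertia_history: list[float] = field(default_factory=list)

    @property
    def inertia(self) -> float:
        return self.inertia_history[-1] if self.inertia_history else float("nan")

    def sizes(self) -> dict[int, int]:
        uniq, cnt = np.unique(self.labels, return_counts=True)
        return {int(u): int(c) for u, c in zip(uniq, cnt)}


def build_matrix(
    tracks: Sequence[CutSiteTrack],
    regions: PeakSet,
    flank: int,
    bins: int,
    anchor: str = "summit",
    track_labels: Sequence[str] | None = None,
) -> SignalMatrix:
    """Mean signal per bin over [anchor - flank, anchor + flank) per region.

    ``anchor`` is "summit" (the peak summit base) or "center" (interval
    midpoint). Windows clipped at contig edges are zero-padded and flagged in
    ``SignalMatrix.clipped``.
    """
    if len(regions) == 0:
        raise ValueError("empty region set")
    if bins < 1:
        raise ValueError("bins must be >= 1")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if anchor not in ("summit", "center"):
        raise ValueError(f"unknown anchor {anchor!r}")
    labels = (
        list(track_labels)
        if track_labels is not None
        else [f"track{i}" for i in range(len(tracks))]
    )
    n = len(regions)
    values = np.zeros((n, len(tracks) * bins), dtype=np.float64)
    clipped = np.zeros(n, dtype=bool)
    for i, peak in enumerate(regions):
        a = peak.summit if anchor == "summit" else peak.interval.midpoint
        lo, hi = a - flank, a + flank
        if lo == hi:
            hi = lo + 1  # degenerate flank=0: single-base window
        for t, track in enumerate(tracks):
            contig = track.counts.get(peak.chrom)
            if contig is None:
                raise ValueError(f"region contig {peak.chrom!r} missing from track")
            if lo < 0 or hi > len(contig):
                clipped[i] = True
            win = track.window(peak.chrom, lo, hi).astype(np.float64)
            for b, chunk in enumerate(np.array_split(win, bins)):
                values[i, t * bins + b] = chunk.mean() if len(chunk) else 0.0
    return SignalMatrix(regions, bins, flank, values, labels, clipped)


def _lloyd(
    x: np.ndarray, centers: np.ndarray, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Lloyd iterations from given centers; returns labels, centers, SSQ trace."""
    k = len(centers)
    labels = np.zeros(len(x), dtype=np.int64)
    history: list[float] = []
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        # empty-cluster repair: seize the point farthest from its center
        for j in range(k):
            if not np.any(new_labels == j):
                far = int(d2[np.arange(len(x)), new_labels].argmax())
                new_labels[far] = j
        history.append(float(d2[np.arange(len(x)), new_labels].sum()))
        for j in range(k):
            centers[j] = x[new_labels == j].mean(axis=0)
        if np.array_equal(new_labels, labels) and len(history) > 1:
            labels = new_labels
            break
        labels = new_labels
    return labels, centers, history


def kmeans_cluster(
    matrix: SignalMatrix | np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 300,
    rank_transform: bool = False,
) -> ClusterAssignment:
    """Seeded k-means over signal-matrix rows.

    Clusters are relabeled in decreasing order of centroid mean signal, so
    cluster 0 is always the strongest group regardless of initialization.
    With ``rank_transform``, each row is rank-transformed before clustering
    (an approximation to rank-based clustering of signal heatmaps).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = matrix.values if isinstance(matrix, SignalMatrix) else np.asarray(matrix)
    x = np.asarray(x, dtype=np.float64)
    if k > len(x):
        raise ValueError(f"k ({k}) exceeds number of regions ({len(x)})")
    if rank_transform:
        x = np.apply_along_axis(rankdata, 1, x)
    rng = np.random.default_rng(seed)
    centers, _ = kmeans_plusplus(
        x, n_clusters=k, random_state=int(rng.integers(2**31 - 1))
    )
    labels, centers, history = _lloyd(x, centers.copy(), max_iter, rng)
    # canonical label order: decreasing centroid mean signal
    order = np.argsort(-centers.mean(axis=1), kind="stable")
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    return ClusterAssignment(
        labels=remap[labels],
        k=k,
        centroids=centers[order],
        seed=seed,
        inertia_history=history,
    )
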