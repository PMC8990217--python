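"""TSS clustering of pooled strand-specific 5'-tag tracks.

CAGE and NET-CAGE reads mark transcription start sites at single-bp
resolution. Nearby same-strand tag positions are grouped into clusters by
gap-based single linkage: two consecutive tag positions belong to one cluster
iff their distance is at most ``max_gap``. Clusters are called on tags pooled
across all libraries of the experiment, then filtered on total pooled support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import defaults
from .intervals import GenomicInterval
from .io import read_ctss


@dataclass
class TagTrack:
    """Sparse strand-specific 5'-tag counts for one library."""

    library_id: str
    tags: pd.DataFrame  # columns: chrom, pos, strand, count

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "strand", "count"}
        if not required.issubset(self.tags.columns):
            raise ValueError(f"TagTrack needs columns {sorted(required)}")
        if len(self.tags) and (self.tags["count"] < 1).any():
            raise ValueError("stored tag counts must be >= 1")

    @classmethod
    def from_ctss(cls, path: str | Path, library_id: str | None = None) -> "TagTrack":
        return cls(library_id or Path(path).stem, read_ctss(path))

    @property
    def total_tags(self) -> int:
        return int(self.tags["count"].sum())


@dataclass(frozen=True)
class TSSCluster:
    """A clustered transcription-initiation unit on one strand."""

    interval: GenomicInterval
    total_tags: int
    summit: int

    def __post_init__(self) -> None:
        if self.total_tags < 1:
            raise ValueError("cluster must have >= 1 supporting tag")
        if not (self.interval.start <= self.summit < self.interval.end):
            raise ValueError("summit must lie within the cluster interval")
        if self.interval.strand not in ("+", "-"):
            raise ValueError("TSS clusters are strand-specific")


def pool_tracks(tracks: Iterable[TagTrack]) -> pd.DataFrame:
    """Sum tag counts per (chrom, pos, strand) across libraries."""
    tracks = list(tracks)
    frames = [t.tags for t in tracks if len(t.tags)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "count"])
    universes = [set(t.tags["chrom"].unique()) for t in tracks if len(t.tags)]
    if len(universes) > 1 and any(u != universes[0] for u in universes[1:]):
        warnings.warn(
            "tag tracks cover different chromosome universes; taking the union",
            stacklevel=2,
        )
    pooled = (
        pd.concat(frames, ignore_index=True)
        .groupby(["chrom", "pos", "strand"], as_index=False)["count"]
        .sum()
    )
    return pooled.sort_values(["chrom", "strand", "pos"], ignore_index=True)


def pool_and_cluster(
    tracks: Sequence[TagTrack],
    max_gap: int = defaults.TSS_CLUSTER_MAX_GAP_BP,
) -> list[TSSCluster]:
    """Cluster pooled tags per (chrom, strand) by single linkage.

    Consecutive tag positions join one cluster iff ``pos[i+1] - pos[i] <=
    max_gap``. The cluster interval spans ``[min_pos, max_pos + 1)``; the
    summit is the position with the highest pooled count, ties broken toward
    the 5'-most position on the cluster's strand.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    pooled = pool_tracks(tracks)
    clusters: list[TSSCluster] = []
    for (chrom, strand), grp in pooled.groupby(["chrom", "strand"], sort=True):
        pos = grp["pos"].to_numpy()
        cnt = grp["count"].to_numpy()
        if len(pos) == 0:
            continue
        breaks = np.nonzero(np.diff(pos) > max_gap)[0] + 1
        for seg_pos, seg_cnt in zip(np.split(pos, breaks), np.split(cnt, breaks)):
            best = seg_cnt.max()
            candidates = seg_pos[seg_cnt == best]
            summit = int(candidates.min() if strand == "+" else candidates.max())
            clusters.append(
                TSSCluster(
                    GenomicInterval(chrom, int(seg_pos[0]), int(seg_pos[-1]) + 1, strand),
                    int(seg_cnt.sum()),
                    summit,
                )
            )
    clusters.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end, c.interval.strand))
    return clusters


def filter_clusters(
    clusters: Sequence[TSSCluster],
    min_tags: int = defaults.MIN_CLUSTER_TAGS,
) -> list[TSSCluster]:
    """Keep clusters with at least *min_tags* pooled supporting tags."""
    if min_tags < 1:
        raise ValueError("min_tags must be >= 1")
    return [c for c in clusters if c.total_tags >= min_tags]


def clusters_to_bed(clusters: Sequence[TSSCluster], path: str | Path) -> None:
    """Emit clusters as BED6 with score = total pooled tags."""
    with open(path, "w") as fh:
        for i, c in enumerate(clusters):
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tcluster{i}\t{c.total_tags}\t{iv.strand}\n"
            )
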