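"""Genomic-interval engine: coordinates, merging, overlap, fixed-width
re-centering and seeded random background placement.

Conventions
-----------
All coordinates are 0-based, half-open (BED). A single 5'-tag position ``p``
is represented as the 1-bp interval ``[p, p+1)``. Strand is one of ``+``,
``-`` or ``.`` (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")

_SORT_KEY = lambda iv: (iv.chrom, iv.start, iv.end)  # noqa: E731


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            label = f" {self.name!r}" if self.name else ""
            raise ValueError(
                f"invalid interval{label}: {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}; expected one of {VALID_STRANDS}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        """Midpoint, floor((start+end)/2); left-of-center for odd lengths."""
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return overlap_length(self, other) > 0


class ChromSizes(dict):
    """Mapping chromosome name -> length in bp; lengths must be positive."""

    def __init__(self, sizes: Mapping[str, int] = ()):
        super().__init__()
        for chrom, length in dict(sizes).items():
            length = int(length)
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
            self[chrom] = length

    def check(self, interval: GenomicInterval) -> None:
        """Raise if *interval* falls outside the known chromosome bounds."""
        if interval.chrom not in self:
            raise KeyError(f"unknown chromosome {interval.chrom!r}")
        if interval.end > self[interval.chrom]:
            raise ValueError(
                f"interval {interval.chrom}:{interval.start}-{interval.end} "
                f"exceeds chromosome length {self[interval.chrom]}"
            )


class RegionSet:
    """An ordered collection of :class:`GenomicInterval` with a sorted flag."""

    def __init__(self, regions: Iterable[GenomicInterval] = ()):
        self.regions: list[GenomicInterval] = list(regions)
        self.is_sorted = all(
            _SORT_KEY(a) <= _SORT_KEY(b) for a, b in zip(self.regions, self.regions[1:])
        )

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, i):
        return self.regions[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, RegionSet) and self.regions == other.regions

    def __repr__(self) -> str:
        return f"RegionSet({len(self)} regions, sorted={self.is_sorted})"

    def sorted(self) -> "RegionSet":
        return RegionSet(sorted(self.regions, key=_SORT_KEY))

    def overlapping(self, query: GenomicInterval) -> list[GenomicInterval]:
        """All member intervals overlapping *query* by >= 1 bp."""
        return [iv for iv in self.regions if iv.overlaps(query)]

    def overlaps_any(self, query: GenomicInterval) -> bool:
        return any(iv.overlaps(query) for iv in self.regions)

    def total_span(self) -> int:
        """Total bp covered after merging (double-counting removed)."""
        return sum(len(iv) for iv in merge(self))


def overlap_length(a: GenomicInterval, b: GenomicInterval) -> int:
    """Base pairs shared by *a* and *b*; 0 when disjoint or on different chroms."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge(regions: RegionSet | Sequence[GenomicInterval], min_gap: int = 0) -> RegionSet:
    """Merge overlapping (and gap <= *min_gap*) intervals into a sorted set.

    With ``min_gap=0`` book-ended intervals merge. Strand and names are
    dropped: a merged interval is an unstranded footprint.
    """
    if min_gap < 0:
        raise ValueError("min_gap must be >= 0")
    ivs = sorted(regions, key=_SORT_KEY)
    out: list[GenomicInterval] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for iv in ivs:
        if iv.chrom == cur_chrom and iv.start - cur_end <= min_gap:
            cur_end = max(cur_end, iv.end)
        else:
            if cur_chrom is not None:
                out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
            cur_chrom, cur_start, cur_end = iv.chrom, iv.start, iv.end
    if cur_chrom is not None:
        out.append(GenomicInterval(cur_chrom, cur_start, cur_end))
    return RegionSet(out)


def extend_to_width(region: GenomicInterval, width: int, sizes: ChromSizes) -> GenomicInterval:
    """Re-center *region* to exactly *width* bp around its midpoint.

    A window that would cross a chromosome boundary is shifted inward so the
    fixed-width guarantee holds (the enrichment statistic assumes equal-length
    regions).
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if region.chrom not in sizes:
        raise KeyError(f"unknown chromosome {region.chrom!r}")
    chrom_len = sizes[region.chrom]
    if chrom_len < width:
        raise ValueError(
            f"chromosome {region.chrom} (length {chrom_len}) shorter than width {width}"
        )
    start = region.midpoint - width // 2
    start = min(max(start, 0), chrom_len - width)
    return replace(region, start=start, end=start + width)


def random_background(
    regions: RegionSet | Sequence[GenomicInterval],
    sizes: ChromSizes,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RegionSet:
    """Length-matched random background regions (bedtools-random semantics).

    Each input interval is re-placed uniformly at random over all valid start
    positions genome-wide: a chromosome is chosen with probability
    proportional to its number of placeable starts (length - L + 1), then the
    start uniformly within it. Background intervals may overlap each other.
    Deterministic for a fixed *seed*.
    """
    if len(sizes) == 0:
        raise ValueError("empty ChromSizes: nowhere to place background regions")
    if rng is None:
        rng = np.random.default_rng(seed)
    chroms = list(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=np.int64)
    out: list[GenomicInterval] = []
    for iv in regions:
        L = len(iv)
        placeable = lengths - L + 1
        weights = np.clip(placeable, 0, None).astype(float)
        if weights.sum() == 0:
            raise ValueError(f"no chromosome can hold an interval of length {L}")
        ci = int(rng.choice(len(chroms), p=weights / weights.sum()))
        start = int(rng.integers(0, placeable[ci]))
        out.append(GenomicInterval(chroms[ci], start, start + L, ".", iv.name))
    return RegionSet(out)
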