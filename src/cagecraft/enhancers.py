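"""Bidirectional transcribed-enhancer calling and promoter annotation.

Active enhancers produce short, divergent, roughly balanced capped RNAs
(eRNAs). A candidate enhancer is a divergent pair of filtered TSS clusters —
a minus-strand cluster lying 5' (left) of a plus-strand cluster with a small
inner gap — whose tag balance, the directionality score
``D = (F - R) / (F + R)``, is close to 0. Clusters near annotated transcript
5' ends are masked out so that ordinary promoters are not called as
enhancers; conversely a promoter call requires the cluster summit to fall
within a fixed flank of a reference 5' end on the matching strand and the
cluster not to overlap any enhancer call, so the two sets are disjoint by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import defaults
from .intervals import GenomicInterval, RegionSet, overlap_length
from .tss import TSSCluster


@dataclass(frozen=True)
class EnhancerCall:
    """A bidirectionally transcribed region spanning a divergent cluster pair."""

    interval: GenomicInterval  # unstranded, [minus.start, plus.end)
    forward_tags: int
    reverse_tags: int

    def __post_init__(self) -> None:
        if self.forward_tags + self.reverse_tags < 1:
            raise ValueError("enhancer call needs >= 1 supporting tag")

    @property
    def directionality(self) -> float:
        return directionality(self.forward_tags, self.reverse_tags)


@dataclass(frozen=True)
class PromoterCall:
    """A TSS cluster assigned to a reference transcript 5' end."""

    cluster: TSSCluster
    target_gene: str | None
    distance_to_5prime: int


def directionality(forward: float, reverse: float) -> float:
    """Tag-balance score (F - R)/(F + R) in [-1, 1]; 0 means fully balanced."""
    total = forward + reverse
    if total <= 0:
        raise ValueError("directionality undefined when F + R = 0")
    return (forward - reverse) / total


def _five_prime_pos(iv: GenomicInterval) -> int:
    """5' end of a reference interval: start on '+', last base on '-'."""
    return iv.start if iv.strand != "-" else iv.end - 1


def call_enhancers(
    clusters: Sequence[TSSCluster],
    window: int = defaults.ENHANCER_WINDOW_BP,
    max_abs_directionality: float = defaults.MAX_ABS_DIRECTIONALITY,
    mask: RegionSet | None = None,
) -> list[EnhancerCall]:
    """Pair divergent TSS clusters into enhancer calls.

    Rules, applied in order:

    1. candidate pairs: minus cluster M and plus cluster P on the same chrom
       with ``P.start >= M.end`` and inner gap ``P.start - M.end <= window``;
    2. each cluster joins at most one pair — partners are assigned greedily by
       smallest gap, ties toward the leftmost pair;
    3. the call spans ``[M.start, P.end)``; F and R are the pooled plus/minus
       tags of all input clusters overlapping that span;
    4. calls with ``|D| >= max_abs_directionality`` are unidirectional and
       dropped;
    5. calls overlapping *mask* (typically reference 5' ends +/- the promoter
       flank) are dropped;
    6. surviving calls that overlap each other are collapsed, keeping the one
       with smallest |D| (ties toward the leftmost) as representative.
    """
    minus = [c for c in clusters if c.interval.strand == "-"]
    plus = [c for c in clusters if c.interval.strand == "+"]

    candidates: list[tuple[int, int, int, TSSCluster, TSSCluster]] = []
    for m in minus:
        for p in plus:
            if p.interval.chrom != m.interval.chrom:
                continue
            gap = p.interval.start - m.interval.end
            if 0 <= gap <= window:
                candidates.append((gap, m.interval.start, p.interval.start, m, p))
    candidates.sort(key=lambda t: t[:3])

    used: set[int] = set()
    raw_calls: list[EnhancerCall] = []
    for gap, _, _, m, p in candidates:
        if id(m) in used or id(p) in used:
            continue
        used.add(id(m))
        used.add(id(p))
        span = GenomicInterval(m.interval.chrom, m.interval.start, p.interval.end)
        fwd = sum(
            c.total_tags
            for c in plus
            if overlap_length(c.interval, span) > 0
        )
        rev = sum(
            c.total_tags
            for c in minus
            if overlap_length(c.interval, span) > 0
        )
        raw_calls.append(EnhancerCall(span, fwd, rev))

    kept = [c for c in raw_calls if abs(c.directionality) < max_abs_directionality]
    if mask is not None:
        kept = [c for c in kept if not mask.overlaps_any(c.interval)]

    # collapse overlapping survivors, keeping the most balanced representative
    kept.sort(key=lambda c: (c.interval.chrom, c.interval.start, c.interval.end))
    merged: list[EnhancerCall] = []
    group: list[EnhancerCall] = []

    def _flush() -> None:
        if group:
            merged.append(
                min(group, key=lambda c: (abs(c.directionality), c.interval.start))
            )

    for call in kept:
        if group and overlap_length(group[-1].interval, call.interval) > 0:
            group.append(call)
        else:
            _flush()
            group = [call]
    _flush()
    return merged


def annotate_promoters(
    clusters: Sequence[TSSCluster],
    five_prime_ends: RegionSet,
    enhancers: Sequence[EnhancerCall],
    flank: int = defaults.PROMOTER_FLANK_BP,
) -> list[PromoterCall]:
    """Assign TSS clusters to reference transcript 5' ends.

    A cluster becomes a promoter iff its summit lies within ``+/- flank`` bp
    of a reference 5' end on the matching strand and its interval overlaps no
    enhancer call. The nearest in-range 5' end wins; the signed distance is
    positive downstream of the 5' end on the cluster's strand.
    """
    enhancer_ivs = [e.interval for e in enhancers]
    calls: list[PromoterCall] = []
    for c in clusters:
        if any(overlap_length(c.interval, iv) > 0 for iv in enhancer_ivs):
            continue
        best: tuple[int, int, str | None] | None = None  # (|dist|, signed, gene)
        for ref in five_prime_ends:
            if ref.chrom != c.interval.chrom:
                continue
            if ref.strand != "." and ref.strand != c.interval.strand:
                continue
            pos = _five_prime_pos(ref)
            offset = c.summit - pos
            if abs(offset) > flank:
                continue
            signed = offset if c.interval.strand == "+" else -offset
            key = (abs(offset), signed, ref.name)
            if best is None or key < best:
                best = key
        if best is not None:
            calls.append(PromoterCall(c, best[2], best[1]))
    return calls


def enhancers_to_bed(calls: Sequence[EnhancerCall], path: str | Path) -> None:
    """BED6 with score = F+R and the directionality score in the name field."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls):
            iv = c.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tenhancer{i};D={c.directionality:.3f}\t"
                f"{c.forward_tags + c.reverse_tags}\t.\n"
            )


def promoters_to_bed(calls: Sequence[PromoterCall], path: str | Path) -> None:
    """BED6 with the assigned gene id in the name field."""
    with open(path, "w") as fh:
        for c in calls:
            iv = c.cluster.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{c.target_gene or '.'}\t"
                f"{c.cluster.total_tags}\t{iv.strand}\n"
            )
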