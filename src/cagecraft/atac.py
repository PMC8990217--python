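"""ATAC-seq peak-set comparison between two conditions.

Per-sample peak calls are union-merged into one peak universe; read counts
per merged peak feed the exact-NB differential machinery, and peaks with an
FDR-adjusted p < alpha are labeled condition-specific in the direction of
their fold change. Peaks are also assigned to genomic feature categories
(promoter > exon > intron > intergenic, by peak midpoint) and compared with
enhancer calls by overlap fraction.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import pandas as pd

from . import defaults
from .intervals import GenomicInterval, RegionSet, merge, overlap_length
from .quantify import CountMatrix, nb_exact_test_bh, rle_norm_factors

#: promoter window around a transcript 5' end, strand-aware (upstream, downstream)
PROMOTER_WINDOW_UP_BP = 1000
PROMOTER_WINDOW_DOWN_BP = 100


def merge_peak_sets(
    per_sample_peaks: Sequence[RegionSet],
    sample_ids: Sequence[str] | None = None,
) -> RegionSet:
    """Union-merge peaks across samples (gap 0: book-ended peaks join).

    Each merged peak's name lists the contributing samples (comma-joined).
    """
    if len(per_sample_peaks) == 0:
        raise ValueError("need at least one sample peak set")
    if sample_ids is None:
        sample_ids = [f"sample{i + 1}" for i in range(len(per_sample_peaks))]
    merged = merge([iv for rs in per_sample_peaks for iv in rs])
    out = []
    for iv in merged:
        contributing = [
            sid
            for sid, rs in zip(sample_ids, per_sample_peaks)
            if any(overlap_length(iv, p) > 0 for p in rs)
        ]
        out.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, ".", ",".join(contributing))
        )
    return RegionSet(out)


def condition_specific_peaks(
    counts: CountMatrix,
    groups: Sequence[str],
    alpha: float = defaults.DE_FDR_ALPHA,
    levels: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Label merged peaks by differential accessibility.

    Runs the exact NB test (condition2 vs condition1); peaks at q < *alpha*
    with higher mean in condition2 are ``activated-specific``, with lower
    mean ``control-specific``, otherwise ``ns``. RLE factors are computed on
    the peak counts when not already attached.
    """
    if counts.norm_factors is None:
        counts = counts.with_factors(rle_norm_factors(counts))
    de = nb_exact_test_bh(counts, groups, alpha=alpha, levels=levels)
    label = de["label"].map(
        {"up": "activated-specific", "down": "control-specific", "ns": "ns"}
    )
    return de.assign(label=label)


def genomic_distribution(
    peaks: RegionSet,
    five_prime_ends: RegionSet,
    exons: RegionSet,
    introns: RegionSet,
) -> pd.Series:
    """Assign each peak to one genomic category by its midpoint.

    Precedence: promoter (within -1000/+100 bp of a transcript 5' end,
    strand-aware) > exon > intron > intergenic. Categories are mutually
    exclusive and exhaustive, so the counts sum to the number of peaks.
    """
    promoter_windows = []
    for ref in five_prime_ends:
        pos = ref.start if ref.strand != "-" else ref.end - 1
        if ref.strand == "-":
            lo, hi = pos - PROMOTER_WINDOW_DOWN_BP, pos + PROMOTER_WINDOW_UP_BP
        else:
            lo, hi = pos - PROMOTER_WINDOW_UP_BP, pos + PROMOTER_WINDOW_DOWN_BP
        promoter_windows.append(GenomicInterval(ref.chrom, max(0, lo), hi + 1))
    promoter_set = RegionSet(promoter_windows)

    counts = {"promoter": 0, "exon": 0, "intron": 0, "intergenic": 0}
    for peak in peaks:
        mid = GenomicInterval(peak.chrom, peak.midpoint, peak.midpoint + 1)
        if promoter_set.overlaps_any(mid):
            counts["promoter"] += 1
        elif exons.overlaps_any(mid):
            counts["exon"] += 1
        elif introns.overlaps_any(mid):
            counts["intron"] += 1
        else:
            counts["intergenic"] += 1
    return pd.Series(counts, name="n_peaks")


def overlap_fraction(a: RegionSet, b: RegionSet) -> float:
    """Fraction of regions in *a* overlapping >= 1 bp of any region in *b*."""
    if len(a) == 0:
        raise ValueError("overlap_fraction of an empty region set is undefined")
    hit = sum(1 for iv in a if b.overlaps_any(iv))
    return hit / len(a)
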