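"""Region-level tag quantification and two-condition differential activity.

Workflow: count 5' tags per region per library (strand-specific for
promoters, strands summed for enhancers), compute relative-log-expression
(RLE, median-of-ratios) normalization factors on the promoter counts, share
those factors with the enhancer counts, floor-filter on prior-count log2-CPM,
and test each feature with a two-sided exact negative-binomial test using a
single common method-of-moments dispersion, followed by Benjamini-Hochberg
FDR adjustment.

The exact test conditions on the feature's total count: with per-library
counts NB(mean mu, variance mu + phi mu^2) and n1/n2 libraries per group, the
group-1 sum given the total T follows a beta-binomial BB(T, n1/phi, n2/phi)
(the binomial B(T, n1/(n1+n2)) in the Poisson limit phi -> 0). The two-sided
p-value sums all outcomes no more probable than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import defaults
from .intervals import RegionSet
from .tss import TagTrack


@dataclass
class CountMatrix:
    """Features x libraries integer counts with library sizes and factors."""

    counts: pd.DataFrame
    library_sizes: pd.Series
    norm_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            raise ValueError("library_sizes missing for some libraries")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        colsums = self.counts.sum(axis=0)
        if (self.library_sizes + 1e-9 < colsums).any():
            raise ValueError("library_sizes must be >= column sums of counts")
        if self.norm_factors is not None:
            self.norm_factors = self.norm_factors.reindex(self.counts.columns)
            if (self.norm_factors <= 0).any():
                raise ValueError("norm_factors must be positive")

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_libraries(self) -> int:
        return self.counts.shape[1]

    def effective_sizes(self) -> pd.Series:
        if self.norm_factors is None:
            raise ValueError("norm_factors not computed; call rle_norm_factors first")
        return self.library_sizes * self.norm_factors

    def with_factors(self, factors: pd.Series) -> "CountMatrix":
        return replace(self, norm_factors=factors)


def _feature_id(iv, i: int) -> str:
    return iv.name if iv.name else f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})#{i}"


def count_tags(
    regions: RegionSet,
    tracks: Sequence[TagTrack],
    mode: str = "stranded",
) -> CountMatrix:
    """Count 5' tags whose position falls in ``[start, end)`` of each region.

    ``stranded`` counts only tags on the region's strand (every region must
    be stranded); ``sum_strands`` counts both strands, as for enhancers. The
    library size is the track's total tag count, not the in-region sum.
    """
    if mode not in ("stranded", "sum_strands"):
        raise ValueError(f"unknown mode {mode!r}")
    if not regions.is_sorted:
        regions = regions.sorted()
    if mode == "stranded":
        for iv in regions:
            if iv.strand == ".":
                raise ValueError(
                    f"unstranded region {iv.chrom}:{iv.start}-{iv.end} in stranded mode"
                )

    feature_ids = [_feature_id(iv, i) for i, iv in enumerate(regions)]
    data = np.zeros((len(regions), len(tracks)), dtype=np.int64)
    for j, track in enumerate(tracks):
        index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        for (chrom, strand), grp in track.tags.groupby(["chrom", "strand"], sort=False):
            g = grp.sort_values("pos")
            pos = g["pos"].to_numpy()
            csum = np.concatenate([[0], np.cumsum(g["count"].to_numpy())])
            index[(chrom, strand)] = (pos, csum)

        def span_sum(chrom: str, strand: str, start: int, end: int) -> int:
            if (chrom, strand) not in index:
                return 0
            pos, csum = index[(chrom, strand)]
            lo = np.searchsorted(pos, start, side="left")
            hi = np.searchsorted(pos, end, side="left")
            return int(csum[hi] - csum[lo])

        for i, iv in enumerate(regions):
            if mode == "stranded":
                data[i, j] = span_sum(iv.chrom, iv.strand, iv.start, iv.end)
            else:
                data[i, j] = span_sum(iv.chrom, "+", iv.start, iv.end) + span_sum(
                    iv.chrom, "-", iv.start, iv.end
                )

    lib_ids = [t.library_id for t in tracks]
    counts = pd.DataFrame(data, index=feature_ids, columns=lib_ids)
    sizes = pd.Series([t.total_tags for t in tracks], index=lib_ids, dtype=float)
    return CountMatrix(counts, sizes)


def rle_norm_factors(promoter_counts: CountMatrix) -> pd.Series:
    """Relative-log-expression (median-of-ratios) normalization factors.

    Rates count/library_size are formed per feature and library; for features
    positive in every library, the library factor is the median over features
    of rate / per-feature geometric-mean rate, rescaled so the factors'
    geometric mean is exactly 1. Effective library size = library_size x
    factor, so the factor corrects for composition on top of raw depth.
    """
    if promoter_counts.n_libraries < 2:
        raise ValueError("RLE factors need >= 2 libraries")
    C = promoter_counts.counts.to_numpy(dtype=float)
    N = promoter_counts.library_sizes.to_numpy(dtype=float)
    all_positive = (C > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no feature is positive in all libraries; cannot compute RLE factors")
    Cp = C[all_positive] / N[None, :]
    log_gm = np.log(Cp).mean(axis=1)
    ratios = Cp / np.exp(log_gm)[:, None]
    factors = np.median(ratios, axis=0)
    factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=promoter_counts.counts.columns, name="norm_factor")


def log2_cpm(counts: CountMatrix, prior: float = defaults.CPM_PRIOR_COUNT) -> pd.DataFrame:
    """log2((count + prior) / effective_library_size * 1e6)."""
    if prior <= 0:
        raise ValueError("prior must be positive")
    eff = counts.effective_sizes()
    if (eff <= 0).any():
        raise ValueError("zero effective library size")
    return np.log2(
        (counts.counts + prior).div(eff, axis=1) * 1e6
    )


def expression_filter(
    logcpm: pd.DataFrame, floor: float, min_libs: int = 1
) -> pd.Series:
    """Keep features with log2-CPM strictly above *floor* in >= *min_libs* libraries."""
    return (logcpm > floor).sum(axis=1) >= min_libs


def promoter_enhancer_log2_cpm(
    promoter_counts: CountMatrix,
    enhancer_counts: CountMatrix,
    prior: float = defaults.CPM_PRIOR_COUNT,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Promoter and enhancer log2-CPM with shared normalization.

    RLE factors are computed on the promoter counts only and applied to both
    matrices: eRNA levels are too low and unstable to anchor normalization,
    so enhancer CPMs use the promoter-derived factors. Returns (promoter
    log2-CPM, enhancer log2-CPM, factors).
    """
    factors = rle_norm_factors(promoter_counts)
    return (
        log2_cpm(promoter_counts.with_factors(factors), prior),
        log2_cpm(enhancer_counts.with_factors(factors), prior),
        factors,
    )


def bh_adjust(pvalues: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def _mom_common_dispersion(adj: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Single common dispersion by method of moments across features.

    Pools (within-group sample variance - mean) against squared means over
    all feature/group pairs with >= 2 libraries; floored at 0.
    """
    num = 0.0
    den = 0.0
    for idx in group_idx:
        if len(idx) < 2:
            continue
        sub = adj[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        num += float((v - m).sum())
        den += float((m**2).sum())
    if den == 0:
        return 0.0
    return max(0.0, num / den)


def _conditional_two_sided_p(s1: int, T: int, n1: int, n2: int, phi: float) -> float:
    """Two-sided exact p for the group-1 sum given the total.

    Sums the conditional probabilities of all outcomes no more probable than
    the observed one (edgeR exactTest convention).
    """
    if T == 0:
        return 1.0
    if phi <= 1e-12:
        if n1 == n2:
            lo, hi = min(s1, T - s1), max(s1, T - s1)
            p = stats.binom.cdf(lo, T, 0.5) + stats.binom.sf(hi - 1, T, 0.5)
            return float(min(1.0, p))
        pmf = stats.binom.pmf(np.arange(T + 1), T, n1 / (n1 + n2))
    else:
        logpmf = stats.betabinom.logpmf(np.arange(T + 1), T, n1 / phi, n2 / phi)
        pmf = np.exp(logpmf - logpmf.max())
        pmf = pmf / pmf.sum()
    p = pmf[pmf <= pmf[s1] * (1 + 1e-12)].sum()
    return float(min(1.0, p))


def nb_exact_test_bh(
    counts: CountMatrix,
    groups: Sequence[str],
    alpha: float = defaults.DE_FDR_ALPHA,
    levels: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Two-sided exact NB test per feature with BH FDR correction.

    *groups* labels each library with one of two conditions; *levels* fixes
    (condition1, condition2) — fold changes are condition2 vs condition1.
    Returns a DataFrame indexed by feature with columns ``logFC``, ``p``,
    ``q`` and ``label`` (up/down at q < *alpha*, else ns).
    """
    groups = pd.Series(list(groups), index=counts.counts.columns)
    if levels is None:
        levels = tuple(sorted(groups.unique()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two conditions, got {levels}")
    idx1 = np.flatnonzero((groups == levels[0]).to_numpy())
    idx2 = np.flatnonzero((groups == levels[1]).to_numpy())
    if len(idx1) == 0 or len(idx2) == 0:
        raise ValueError("both conditions need at least one library")
    if len(idx1) < 2 or len(idx2) < 2:
        raise ValueError("need >= 2 libraries per condition")

    eff = counts.effective_sizes().to_numpy(dtype=float)
    C = counts.counts.to_numpy(dtype=float)
    gm_eff = np.exp(np.mean(np.log(eff)))
    adj = C * (gm_eff / eff)[None, :]

    nonzero = C.sum(axis=1) > 0
    phi = _mom_common_dispersion(adj[nonzero], [idx1, idx2])

    n1, n2 = len(idx1), len(idx2)
    s1 = np.rint(adj[:, idx1].sum(axis=1)).astype(np.int64)
    s2 = np.rint(adj[:, idx2].sum(axis=1)).astype(np.int64)

    pvals = np.ones(counts.n_features)
    for i in np.flatnonzero(nonzero):
        pvals[i] = _conditional_two_sided_p(int(s1[i]), int(s1[i] + s2[i]), n1, n2, phi)

    prior = defaults.CPM_PRIOR_COUNT
    logfc = np.log2((adj[:, idx2].mean(axis=1) + prior) / (adj[:, idx1].mean(axis=1) + prior))
    logfc[~nonzero] = 0.0

    qvals = bh_adjust(pvals)
    label = np.where(
        (qvals < alpha) & (logfc > 0), "up", np.where((qvals < alpha) & (logfc < 0), "down", "ns")
    )
    return pd.DataFrame(
        {"logFC": logfc, "p": pvals, "q": qvals, "label": label},
        index=counts.counts.index,
    )
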