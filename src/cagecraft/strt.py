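"""Single-cell 5' STRT differential expression.

Stages: (1) a genes-per-cell QC filter with the first quartile of the
distribution reported as the recommended cutoff; (2) ERCC spike-in depth
normalization — every cell's gene counts are binomially downsampled to the
minimum spike-in total over cells, averaged over ``nresamp`` replicates, so
spike-ins act as a per-cell depth anchor; (3) a two-class unpaired rank test:
a standardized Wilcoxon rank-sum statistic per gene, with significance from
the empirical distribution of the statistic under random label permutations
and a plug-in FDR (pi0 fixed at 1, conservative).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from . import defaults


@dataclass
class SingleCellCounts:
    """Gene and spike-in counts (rows) by cells (columns) with group labels."""

    genes: pd.DataFrame
    spikes: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if list(self.genes.columns) != list(self.spikes.columns):
            raise ValueError("gene and spike matrices must share the same cells")
        self.groups = self.groups.reindex(self.genes.columns)
        if self.groups.isna().any():
            raise ValueError("group labels missing for some cells")
        if (self.genes.to_numpy() < 0).any() or (self.spikes.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.genes.shape[1]

    def spike_totals(self) -> pd.Series:
        return self.spikes.sum(axis=0)


def genes_per_cell(counts: SingleCellCounts) -> pd.Series:
    """Number of expressed genes (count >= 1) per cell."""
    return (counts.genes >= 1).sum(axis=0)


def q1_genes_per_cell(counts: SingleCellCounts) -> float:
    """First quartile of the genes-per-cell distribution (linear interpolation)."""
    return float(np.quantile(genes_per_cell(counts).to_numpy(), 0.25))


def qc_filter_cells(counts: SingleCellCounts, min_genes: float) -> SingleCellCounts:
    """Drop cells expressing fewer than *min_genes* genes.

    ``q1_genes_per_cell`` gives the distribution's first quartile as the
    recommended cutoff. Raises when no cell survives.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    gpc = genes_per_cell(counts)
    keep = gpc[gpc >= min_genes].index
    if len(keep) == 0:
        raise ValueError(
            f"all {counts.n_cells} cells fall below min_genes={min_genes} "
            f"(genes-per-cell range {gpc.min()}-{gpc.max()}, Q1={q1_genes_per_cell(counts):.1f})"
        )
    return replace(
        counts,
        genes=counts.genes[keep],
        spikes=counts.spikes[keep],
        groups=counts.groups.loc[keep],
    )


def spikein_normalize(
    counts: SingleCellCounts,
    nresamp: int = defaults.SPIKE_NRESAMP,
    seed: int | None = None,
) -> pd.DataFrame:
    """Downsample every cell to the minimum spike-in depth.

    Target depth is the minimum spike-in total over cells; each cell's gene
    counts are binomially thinned at rate target/spike_total, independently
    *nresamp* times, and the per-gene mean over replicates is returned
    (non-integer values allowed). Deterministic for a fixed *seed*.
    """
    if nresamp < 1:
        raise ValueError("nresamp must be >= 1")
    totals = counts.spike_totals()
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero spike-in total for cells {bad}; filter them out first")
    target = float(totals.min())
    rng = np.random.default_rng(seed)
    out = np.empty(counts.genes.shape, dtype=float)
    gene_mat = counts.genes.to_numpy(dtype=np.int64)
    for j, cell in enumerate(counts.genes.columns):
        rate = target / float(totals[cell])
        draws = rng.binomial(gene_mat[:, j][None, :].repeat(nresamp, axis=0), rate)
        out[:, j] = draws.mean(axis=0)
    return pd.DataFrame(out, index=counts.genes.index, columns=counts.genes.columns)


def _rank_stats(norm: np.ndarray, group2_indicator: np.ndarray) -> np.ndarray:
    """Standardized Wilcoxon rank-sum statistics, one column per label vector.

    *group2_indicator* is cells x k (k label assignments); ranks are computed
    once per gene, so permuted statistics come from a single matrix product.
    Genes whose null variance is zero (all values tied) get statistic 0.
    """
    m, n = norm.shape
    ranks = rankdata(norm, axis=1)
    n2 = group2_indicator.sum(axis=0)
    n1 = n - n2
    expect = n2 * (n + 1) / 2.0

    # tie correction: sum of (t^3 - t) over tie groups, per gene
    tie_term = np.zeros(m)
    srt = np.sort(norm, axis=1)
    for i in range(m):
        _, counts_i = np.unique(srt[i], return_counts=True)
        tie_term[i] = float((counts_i**3 - counts_i).sum())
    var = (n1 * n2 / 12.0)[None, :] * ((n + 1) - tie_term[:, None] / (n * (n - 1)))

    w = ranks @ group2_indicator
    with np.errstate(invalid="ignore", divide="ignore"):
        stats = (w - expect[None, :]) / np.sqrt(var)
    stats[~np.isfinite(stats)] = 0.0
    return stats


def samseq_wilcoxon(
    norm_counts: pd.DataFrame,
    groups: Sequence[str],
    nperms: int = defaults.WILCOXON_NPERMS,
    fdr: float = defaults.DE_FDR_ALPHA,
    seed: int | None = None,
    levels: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Rank-sum test with permutation plug-in FDR (SAM-style, two-class unpaired).

    Per gene the statistic is the standardized Wilcoxon rank-sum of the
    second class (positive = higher in condition2); when resampled counts are
    supplied the replicate-averaged values are ranked. The null is the
    empirical distribution of the statistics under *nperms* random label
    permutations; for a symmetric cutoff t,
    ``FDR(t) = median_perms #{ |stat*| >= t } / #{ |stat| >= t }``
    with pi0 fixed at 1, and a gene's q is the smallest FDR over cutoffs
    t <= |stat_gene|. Genes are called up/down at q < *fdr*.
    """
    if nperms < 1:
        raise ValueError("nperms must be >= 1")
    groups = pd.Series(list(groups), index=norm_counts.columns)
    if levels is None:
        levels = tuple(sorted(groups.unique()))
    if len(levels) != 2:
        raise ValueError(f"need exactly two classes, got {levels}")
    is2 = (groups == levels[1]).to_numpy()
    n2 = int(is2.sum())
    n1 = norm_counts.shape[1] - n2
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 cells per class")

    norm = norm_counts.to_numpy(dtype=float)
    n = norm.shape[1]
    rng = np.random.default_rng(seed)
    # permute the label vector itself: swapping the two class names then
    # yields complement subsets, leaving |stat*| and hence q unchanged
    indicators = np.zeros((n, nperms + 1))
    indicators[is2, 0] = 1.0
    for k in range(nperms):
        indicators[:, k + 1] = is2[rng.permutation(n)]

    stats = _rank_stats(norm, indicators)
    obs = stats[:, 0]
    perm_abs = np.abs(stats[:, 1:])

    s = np.abs(obs)
    order = np.argsort(s, kind="mergesort")
    s_sorted = s[order]
    m = len(s)
    # number of genes at or above each observed threshold
    obs_counts = m - np.searchsorted(s_sorted, s_sorted, side="left")
    perm_counts = np.empty((nperms, m))
    for k in range(nperms):
        col = np.sort(perm_abs[:, k])
        perm_counts[k] = m - np.searchsorted(col, s_sorted, side="left")
    med_counts = np.median(perm_counts, axis=0)
    fdr_at = np.minimum(1.0, med_counts / obs_counts)
    # q = min FDR over cutoffs t <= |stat|: prefix-min in ascending order,
    # read at the last index sharing the gene's threshold so ties agree
    prefix_min = np.minimum.accumulate(fdr_at)
    last_at = np.searchsorted(s_sorted, s, side="right") - 1
    q = prefix_min[last_at]

    direction = np.where(
        (q < fdr) & (obs > 0), "up", np.where((q < fdr) & (obs < 0), "down", "ns")
    )
    return pd.DataFrame(
        {"statistic": obs, "q": q, "direction": direction}, index=norm_counts.index
    )
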