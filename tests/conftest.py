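import numpy as np
import pytest

import cagecraft as cg


@pytest.fixture(scope="session")
def sim_config():
    return cg.SimConfig(master_seed=11)


@pytest.fixture(scope="session")
def landscape(sim_config):
    return cg.simulate_regulatory_landscape(sim_config)


@pytest.fixture(scope="session")
def cage_data(sim_config, landscape):
    return cg.simulate_cage_atac(sim_config, landscape)


@pytest.fixture(scope="session")
def filtered_clusters(cage_data):
    return cg.filter_clusters(cg.pool_and_cluster(cage_data.tracks))


@pytest.fixture(scope="session")
def tss_mask(landscape):
    """Reference 5' ends +/- the promoter flank, used to mask enhancer calls."""
    flank = cg.defaults.PROMOTER_FLANK_BP
    return cg.RegionSet(
        cg.GenomicInterval(r.chrom, max(0, r.start - flank), r.end + flank)
        for r in landscape.five_prime_ends
    )


@pytest.fixture(scope="session")
def enhancer_calls(filtered_clusters, tss_mask):
    return cg.call_enhancers(filtered_clusters, mask=tss_mask)


@pytest.fixture(scope="session")
def promoter_calls(filtered_clusters, landscape, enhancer_calls):
    return cg.annotate_promoters(
        filtered_clusters, landscape.five_prime_ends, enhancer_calls
    )


def make_intervals(rng, n, chrom_len=10_000, chroms=("chrA", "chrB")):
    """Random small intervals for oracle-equivalence tests."""
    out = []
    for _ in range(n):
        chrom = chroms[rng.integers(len(chroms))]
        start = int(rng.integers(0, chrom_len - 1))
        end = int(rng.integers(start + 1, min(chrom_len, start + 1 + rng.integers(1, 400))))
        out.append(cg.GenomicInterval(chrom, start, end))
    return out


def coverage_merge_oracle(intervals, chrom_len=10_000):
    """Per-bp boolean coverage sweep: the brute-force merge (gap 0)."""
    by_chrom = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, np.zeros(chrom_len, dtype=bool))[iv.start : iv.end] = True
    out = []
    for chrom in sorted(by_chrom):
        cov = by_chrom[chrom]
        padded = np.concatenate([[False], cov, [False]]).astype(np.int8)
        edges = np.flatnonzero(np.diff(padded))
        for s, e in zip(edges[::2], edges[1::2]):
            out.append(cg.GenomicInterval(chrom, int(s), int(e)))
    return out
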