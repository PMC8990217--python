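"""End-to-end benchmark computations on seeded synthetic data.

Each function regenerates its inputs from scratch through :mod:`cagecraft.synth`,
runs the corresponding pipeline stage at the default thresholds, and measures
recovery or calibration against the planted truth. These power both the test
suite and ``scripts/acceptance.py``; problem sizes are chosen so the whole set
runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import defaults
from .enhancers import annotate_promoters, call_enhancers
from .intervals import ChromSizes, GenomicInterval, RegionSet, merge, overlap_length, random_background
from .quantify import CountMatrix, log2_cpm, nb_exact_test_bh, rle_norm_factors
from .repeats import enrichment_profile
from .strt import samseq_wilcoxon, spikein_normalize
from .synth import SimConfig, simulate_cage_atac, simulate_regulatory_landscape, simulate_strt
from .tss import filter_clusters, pool_and_cluster


def _child_seeds(seed: int, n: int) -> list[int]:
    """Derive *n* independent 31-bit seeds from one master seed."""
    return [int(s) % 2**31 for s in np.random.SeedSequence(int(seed)).generate_state(n)]


def enhancer_recovery(seed: int) -> dict:
    """Planted-enhancer recovery of the full CAGE calling chain.

    Default benchmark genome (3 x 1 Mb, 300 promoters, 200 enhancers, 4+4
    libraries); returns sensitivity/precision of the enhancer caller against
    the planted intervals, plus promoter-call counts and the number of
    promoter/enhancer overlaps (zero by construction).
    """
    config = SimConfig(master_seed=seed)
    landscape = simulate_regulatory_landscape(config)
    cage = simulate_cage_atac(config, landscape)
    clusters = filter_clusters(pool_and_cluster(cage.tracks))
    flank = defaults.PROMOTER_FLANK_BP
    mask = RegionSet(
        GenomicInterval(r.chrom, max(0, r.start - flank), r.end + flank)
        for r in landscape.five_prime_ends
    )
    calls = call_enhancers(clusters, mask=mask)
    promoters = annotate_promoters(clusters, landscape.five_prime_ends, calls)

    truth = landscape.truth.enhancer_regions()
    sens = sum(1 for t in truth if any(c.interval.overlaps(t) for c in calls)) / len(truth)
    prec = sum(1 for c in calls if truth.overlaps_any(c.interval)) / max(1, len(calls))
    overlaps = sum(
        1
        for p in promoters
        for e in calls
        if overlap_length(p.cluster.interval, e.interval) > 0
    )
    return {
        "sensitivity": sens,
        "precision": prec,
        "n_enhancer_calls": len(calls),
        "n_promoter_calls": len(promoters),
        "n_planted_enhancers": len(truth),
        "promoter_enhancer_overlaps": overlaps,
    }


def _mc_hit_rate(
    repeats_df: pd.DataFrame, sizes: ChromSizes, width: int, n_draws: int, seed: int
) -> float:
    """Monte-Carlo chance that a uniform *width*-bp window touches any element.

    Independent of the assignment machinery: merged element intervals per
    chromosome, vectorized searchsorted overlap test on raw uniform draws.
    """
    rng = np.random.default_rng(seed)
    chroms = list(sizes)
    lengths = np.array([sizes[c] for c in chroms], dtype=float)
    placeable = lengths - width + 1
    probs = placeable / placeable.sum()
    choice = rng.choice(len(chroms), size=n_draws, p=probs)
    hits = 0
    for ci, chrom in enumerate(chroms):
        n_c = int((choice == ci).sum())
        if n_c == 0:
            continue
        starts_q = rng.integers(0, int(placeable[ci]), n_c)
        sub = repeats_df[repeats_df["chrom"] == chrom]
        merged = merge(
            [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(sub["start"], sub["end"])]
        )
        r_start = np.array([iv.start for iv in merged])
        r_end = np.array([iv.end for iv in merged])
        if len(r_start) == 0:
            continue
        idx = np.searchsorted(r_start, starts_q + width, side="left")
        hit = (idx > 0) & (r_end[np.maximum(idx - 1, 0)] > starts_q)
        hits += int(hit.sum())
    return hits / n_draws


def repeat_enrichment_benchmark(seed: int, n_oracle_draws: int = 100_000) -> dict:
    """Planted and null repeat-family enrichment on a 3 x 3 Mb genome.

    Planted: one family at 5% genome coverage additionally placed under 40%
    of 1000 regulatory regions; the measured log2 ratio is compared with the
    Monte-Carlo expectation log2((p + (1-p) h) / h), where h is the chance
    hit rate of a random 600 bp window. Null: a family tiled at 10% coverage
    scored over 1000 random regions.
    """
    s_land, s_prof, s_mc, s_null, s_roi = _child_seeds(seed, 5)
    planted_p = 0.4
    config = SimConfig(
        master_seed=s_land,
        chrom_lengths={"chr1": 3_000_000, "chr2": 3_000_000, "chr3": 3_000_000},
        n_promoters=0,
        n_enhancers=1000,
        repeat_families={
            "ERVL-MaLR": {"coverage": 0.05, "planted_prob": planted_p, "element_length": 300}
        },
    )
    landscape = simulate_regulatory_landscape(config)
    regions = landscape.truth.enhancer_regions()
    prof = enrichment_profile(
        regions, landscape.repeats, landscape.sizes, n_draws=10, seed=s_prof
    )
    planted_log2 = float(prof.table.loc["ERVL-MaLR", "log2_ratio"])

    width = defaults.REPEAT_REGION_WIDTH_BP
    hit = _mc_hit_rate(landscape.repeats.df, landscape.sizes, width, n_oracle_draws, s_mc)
    expected_log2 = float(np.log2((planted_p + (1 - planted_p) * hit) / hit))

    null_config = SimConfig(
        master_seed=s_null,
        chrom_lengths=dict(config.chrom_lengths),
        n_promoters=0,
        n_enhancers=10,
        repeat_families={"MIR": {"coverage": 0.10, "planted_prob": 0.0, "element_length": 200}},
    )
    null_land = simulate_regulatory_landscape(null_config)
    roi = random_background(
        RegionSet([GenomicInterval("chr1", 0, width)] * 1000), null_land.sizes, seed=s_roi
    )
    null_prof = enrichment_profile(roi, null_land.repeats, null_land.sizes, n_draws=10, seed=s_roi)
    null_log2 = float(null_prof.table.loc["MIR", "log2_ratio"])

    return {
        "planted_log2_ratio": planted_log2,
        "expected_log2_ratio": expected_log2,
        "null_log2_ratio": null_log2,
        "n_regions": len(regions),
    }


def normalization_benchmark(seed: int, n_seeds: int = 20) -> dict:
    """RLE depth recovery, exact unit geometric mean, exact log2-CPM floor.

    No-DE Poisson matrices with per-library depth factors in [0.5, 2] and
    equal declared library sizes: the factors must recover the depths. Also
    reports the worst deviation of the factors' geometric mean from 1 and the
    log2-CPM of a zero count (prior 0.25, effective size 1e6).
    """
    rel_errs = []
    gm_devs = []
    for s in _child_seeds(seed, n_seeds):
        rng = np.random.default_rng(s)
        depth = rng.uniform(0.5, 2.0, size=6)
        counts = rng.poisson(200.0 * depth[None, :], size=(2000, 6))
        df = pd.DataFrame(counts, columns=[f"L{j}" for j in range(6)])
        cm = CountMatrix(df, pd.Series(1e6, index=df.columns))
        f = rle_norm_factors(cm).to_numpy()
        target = depth / np.exp(np.mean(np.log(depth)))
        rel_errs.append(float(np.max(np.abs(f - target) / target)))
        gm_devs.append(abs(float(np.exp(np.mean(np.log(f)))) - 1.0))

    zero_cm = CountMatrix(
        pd.DataFrame({"L0": [0]}), pd.Series({"L0": 1e6})
    ).with_factors(pd.Series({"L0": 1.0}))
    log2cpm_zero = float(log2_cpm(zero_cm, prior=defaults.CPM_PRIOR_COUNT).iloc[0, 0])
    return {
        "max_factor_rel_error_pct": 100.0 * max(rel_errs),
        "max_geomean_deviation": max(gm_devs),
        "log2_cpm_zero_count": log2cpm_zero,
    }


def de_error_control_benchmark(seed: int, n_seeds: int = 20) -> dict:
    """Exact-NB test calibration and planted recovery (2000 features, 4 vs 4).

    Null: Poisson counts, raw-p rejection at alpha=0.05 averaged over
    *n_seeds* seeds plus the mean number of q<0.05 calls. Planted: NB
    (dispersion 0.1, baseline 100) with 100 features 4-fold up.
    """
    groups = ["a"] * 4 + ["b"] * 4
    seeds = _child_seeds(seed, n_seeds + 1)
    rates, qcalls = [], []
    for s in seeds[:-1]:
        rng = np.random.default_rng(s)
        df = pd.DataFrame(rng.poisson(1000, size=(2000, 8)), columns=[f"L{j}" for j in range(8)])
        cm = CountMatrix(df, df.sum(axis=0).astype(float))
        cm = cm.with_factors(rle_norm_factors(cm))
        de = nb_exact_test_bh(cm, groups)
        rates.append(float((de["p"] < 0.05).mean()))
        qcalls.append(int((de["q"] < 0.05).sum()))

    rng = np.random.default_rng(seeds[-1])
    r = 1 / 0.1
    mean = np.full((2000, 8), 100.0)
    mean[:100, 4:] *= 4
    df = pd.DataFrame(rng.negative_binomial(r, r / (r + mean)), columns=[f"L{j}" for j in range(8)])
    cm = CountMatrix(df, df.sum(axis=0).astype(float))
    cm = cm.with_factors(rle_norm_factors(cm))
    de = nb_exact_test_bh(cm, groups, levels=("a", "b"))
    sens = float((de["label"].iloc[:100] == "up").mean())
    return {
        "null_rejection_rate": float(np.mean(rates)),
        "null_rejection_se_band": 3 * float(np.sqrt(0.05 * 0.95 / (2000 * n_seeds))),
        "mean_q05_calls": float(np.mean(qcalls)),
        "planted_sensitivity": sens,
    }


def strt_benchmark(seed: int, n_null_seeds: int = 10) -> dict:
    """Spike-in normalization fidelity and rank-test error control.

    (1) A two-cell binomial oracle: the cell at twice the target spike depth
    must halve its gene-count total within 3 SE. (2) Global null (no planted
    genes, 12 vs 15 cells): significant calls per seed. (3) Planted 4-fold
    shifts in 100 of 2000 genes: empirical FDP and sensitivity at q < 0.05.
    """
    s_spike, s_planted, s_norm, s_test, *null_seeds = _child_seeds(seed, 4 + n_null_seeds)

    rng = np.random.default_rng(s_spike)
    genes = rng.poisson(50, size=(2000, 2))
    sc2 = _two_cell_counts(genes)
    norm = spikein_normalize(sc2, nresamp=defaults.SPIKE_NRESAMP, seed=s_spike)
    total_raw = float(genes[:, 1].sum())
    total_norm = float(norm.iloc[:, 1].sum())
    se = float(np.sqrt(total_raw * 0.25 / defaults.SPIKE_NRESAMP))
    halving_z = abs(total_norm - 0.5 * total_raw) / se

    null_calls = []
    for s in null_seeds:
        cfg = SimConfig(master_seed=s, sc_n_de_genes=0)
        sc, _ = simulate_strt(cfg)
        norm = spikein_normalize(sc, seed=s)
        res = samseq_wilcoxon(norm, sc.groups, seed=s, levels=("control", "knockdown"))
        null_calls.append(int((res["direction"] != "ns").sum()))

    cfg = SimConfig(master_seed=s_planted)
    sc, de_map = simulate_strt(cfg)
    norm = spikein_normalize(sc, seed=s_norm)
    res = samseq_wilcoxon(norm, sc.groups, seed=s_test, levels=("control", "knockdown"))
    called = res[res["direction"] != "ns"]
    tp = sum(1 for g in called.index if g in de_map)
    sign_ok = sum(
        1
        for g in called.index
        if g in de_map and (de_map[g] > 0) == (called.loc[g, "direction"] == "up")
    )
    return {
        "spike_halving_ratio": total_norm / total_raw,
        "spike_halving_z": float(halving_z),
        "null_false_calls_max": max(null_calls),
        "null_false_calls_mean": float(np.mean(null_calls)),
        "planted_fdp": (len(called) - tp) / max(1, len(called)),
        "planted_sensitivity": tp / len(de_map),
        "planted_sign_agreement": sign_ok / max(1, tp),
    }


def _two_cell_counts(genes: np.ndarray):
    from .strt import SingleCellCounts

    cells = ["c1", "c2"]
    spikes = np.array([[25, 50]]).repeat(4, axis=0)  # totals 100 vs 200
    return SingleCellCounts(
        pd.DataFrame(genes, index=[f"g{i}" for i in range(genes.shape[0])], columns=cells),
        pd.DataFrame(spikes, index=[f"s{i}" for i in range(4)], columns=cells),
        pd.Series(["a", "a"], index=cells),
    )
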