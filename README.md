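# cagecraft

A tested, reusable Python pipeline for the regulatory-genomics computations
used to characterize transcription-factor-driven embryonic-genome-activation
programs in human embryonic stem cells: calling transcribed promoters and
enhancers from CAGE/NET-CAGE 5′-tag data, testing their differential activity
between two conditions, measuring transposable-element family enrichment
under regulatory regions against a matched random background, comparing ATAC
peak sets, and running spike-in-normalized single-cell 5′ STRT differential
expression. It is aimed at computational biologists who want these analysis
steps as plain, seeded, unit-tested functions rather than a chain of
one-off shell scripts.

## What it computes

**TSS clustering and enhancer calling.** 5′ tags pooled across libraries are
grouped per strand by single linkage (consecutive tag positions ≤ 20 bp
apart), and clusters with ≥ 3 supporting tags are retained. A transcribed
enhancer is a divergent cluster pair — minus-strand cluster 5′ of a
plus-strand cluster, inner gap ≤ 400 bp — whose tag balance

    D = (F − R) / (F + R)

satisfies |D| < 0.8 (balanced bidirectional transcription), away from
annotated transcript 5′ ends. A promoter is a cluster whose summit lies
within ±300 bp of an annotated 5′ end on the same strand and that overlaps no
enhancer, so the two sets are disjoint by construction.

**Differential activity.** Tags are counted per region per library
(strand-specific for promoters, strands summed for enhancers), normalized
with relative-log-expression (median-of-ratios) factors computed on
promoters and shared with enhancers, floored on prior-count log2 CPM
(prior 0.25; floors −2.0 for promoters, −3.5 for enhancers), and tested per
feature with a two-sided exact negative-binomial test. Conditioned on a
feature's total count T, the group-1 sum follows a beta-binomial
BB(T, n₁/φ, n₂/φ) with a single method-of-moments dispersion φ; p-values are
BH-adjusted and features called up/down at q < 0.05.

**Repeat enrichment.** Regions are re-centered to exactly 600 bp, each is
assigned to the repeat element with the longest base-pair overlap, and
per-family hit frequencies are compared with those of random background
regions of identical number and length:
`log2((obs + 0.5) / (background + 0.5))`.

**Single-cell STRT.** Cells are QC-filtered on expressed genes (first
quartile reported as the recommended cutoff), gene counts are binomially
downsampled to the minimum ERCC spike-in depth averaged over 1000 resampling
replicates, and differential expression uses a standardized Wilcoxon
rank-sum statistic with significance from 1000 label permutations and a
plug-in FDR (π₀ = 1).

A seeded synthetic-data generator (`cagecraft.synth`) produces every input
the pipeline consumes — promoter tag pileups, balanced divergent enhancer
pairs, background tags, two-condition ATAC counts, repeat families with
planted enrichment, single-cell counts with spike-in depth anchors — with
the planted truth serialized alongside, so every stage is tested end to end
against known ground truth.

## Worked example

```python
import cagecraft as cg

cfg = cg.SimConfig(master_seed=1)            # 3 x 1 Mb genome, 300 genes, 200 enhancers
land = cg.simulate_regulatory_landscape(cfg)
cage = cg.simulate_cage_atac(cfg, land)      # 4 control + 4 activated libraries

clusters = cg.filter_clusters(cg.pool_and_cluster(cage.tracks))
mask = cg.RegionSet(
    cg.GenomicInterval(r.chrom, max(0, r.start - 300), r.end + 300)
    for r in land.five_prime_ends
)
enhancers = cg.call_enhancers(clusters, mask=mask)
promoters = cg.annotate_promoters(clusters, land.five_prime_ends, enhancers)
print(f"{len(clusters)} TSS clusters -> {len(promoters)} promoters, {len(enhancers)} enhancers")

prom = cg.count_tags(cg.RegionSet([p.cluster.interval for p in promoters]).sorted(),
                     cage.tracks, "stranded")
enh = cg.count_tags(cg.RegionSet([e.interval for e in enhancers]).sorted(),
                    cage.tracks, "sum_strands")
lp, le, factors = cg.promoter_enhancer_log2_cpm(prom, enh)
de = cg.nb_exact_test_bh(prom.with_factors(factors), cage.groups,
                         levels=("control", "activated"))
print("promoter DE labels:", de["label"].value_counts().to_dict())

prof = cg.enrichment_profile(land.truth.enhancer_regions(), land.repeats, land.sizes, seed=1)
print(prof.table.round(3))
```

prints

```
701 TSS clusters -> 300 promoters, 200 enhancers
promoter DE labels: {'ns': 257, 'up': 32, 'down': 11}
           observed_frequency  background_frequency  log2_ratio
family
ERVL-MaLR               0.505                 0.168       1.569
MIR                     0.095                 0.166      -0.789
```

All 300 planted promoters and all 200 planted enhancers are recovered; the
32 promoters called "up" are a subset of the 82 planted activated promoters
(the exact test at 4 vs 4 libraries and ~20 tags per library has limited
power; no non-activated promoter is called up). The repeat family planted
under 40% of enhancers shows a ~3-fold (log2 ≈ 1.6) enrichment over its
matched random background, while the uniformly tiled MIR family does not.

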