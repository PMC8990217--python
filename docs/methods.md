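# Methods

This note documents the models and procedures implemented in `cagecraft`,
the parameter choices that matter, what the synthetic-data generator does
and does not emulate, and the numerical decisions taken where the design was
genuinely open. No empirical claim here goes beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinates and interval primitives

All coordinates are 0-based, half-open (BED convention); a CTSS tag position
`p` is the 1-bp interval `[p, p+1)`. The midpoint of an interval is
`floor((start+end)/2)`, i.e. the left-of-center base for odd lengths.

`merge` is a sorted sweep that fuses intervals overlapping or separated by at
most `min_gap` bases; with the default `min_gap = 0`, book-ended intervals
fuse. `extend_to_width` re-centers a region to an exact width; a window that
would cross a chromosome end is shifted inward rather than clipped, because
the repeat-enrichment statistic assumes equal-length regions. Both are
verified against brute-force oracles (per-bp coverage sweeps and pairwise
fix-point fusion) on thousands of random instances.

`random_background` reproduces bedtools-random semantics: each input
interval is re-placed with its exact length, choosing a chromosome with
probability proportional to its number of valid start positions and the
start uniformly within it. Background intervals may overlap one another and
no assembly-gap exclusion list is applied (none is defined for the toy
genomes this package targets). All placement is driven by a seeded
generator; uniformity is checked by chi-square goodness of fit.

## TSS clustering

Tags are pooled across all libraries of an experiment before clustering.
Clustering is gap-based single linkage per (chromosome, strand): consecutive
tag positions join one cluster when `pos[i+1] − pos[i] ≤ max_gap`, with
`max_gap = 20` bp by default. The cluster interval spans the member
positions; the summit is the position of maximal pooled count, ties broken
toward the 5′-most position on the cluster's strand. Clusters need ≥ 3
pooled supporting tags to be retained.

Choices made here: decomposition-based peak identification (which fits and
splits multi-modal clusters) is deliberately replaced by plain single
linkage — it is deterministic, order-free, has one interpretable parameter,
and matches the operational notion of tags "mapping close to each other on
the same strand". Pooling before clustering (rather than per-sample
clustering followed by unification) is a simplification; it changes cluster
boundaries only where single libraries disagree by more than the gap.

## Enhancer and promoter calling

A candidate enhancer is a divergent pair: a minus-strand cluster whose end
lies at most `window = 400` bp before the start of a plus-strand cluster.
Each cluster joins at most one pair; partners are assigned greedily by
smallest inner gap (ties toward the leftmost pair). The call spans from the
minus cluster's start to the plus cluster's end; F and R are the pooled
plus- and minus-strand tags of all clusters overlapping that span, and the
directionality score is D = (F − R)/(F + R). Calls with |D| ≥ 0.8 are
treated as unidirectional and dropped; calls overlapping the mask
(reference transcript 5′ ends ± 300 bp, the same flank used for promoter
assignment) are dropped; overlapping survivors are collapsed, keeping the
most balanced (smallest |D|) call. The window and directionality defaults
follow the published defaults of the standard bidirectional-eRNA calling
method this module re-implements.

A promoter call requires the cluster summit within ± 300 bp of a reference
5′ end on the matching strand (the 5′ end of a minus-strand reference
interval is its last base) and no overlap with any enhancer call, so the
promoter and enhancer sets are disjoint by construction — asserted on every
benchmark run. Signed distances are reported downstream-positive on the
cluster's strand. The nearest in-range 5′ end wins; exact ties prefer the
smaller absolute offset, then the downstream side, then the lexicographically
smaller transcript id.

## Quantification and differential activity

Counting is strand-specific for promoters and strand-summed for enhancers;
a tag is in a region when its position falls in `[start, end)`. Library
sizes are total track tag counts, not in-region sums.

Normalization uses relative log expression (median-of-ratios) computed on
promoter counts only: per-feature rates count/library-size, geometric-mean
reference across libraries, per-library factor = median ratio over features
positive in every library, rescaled so the factors' geometric mean is
exactly 1. Enhancer CPMs reuse the promoter-derived factors — eRNA levels
are too low and unstable to anchor normalization. log2 CPM adds a flat
prior count of 0.25 per observation before dividing by the effective
library size (library size × factor); features must exceed −2.0
(promoters) or −3.5 (enhancers) log2 CPM in at least one library.

The two-condition test is a two-sided exact negative-binomial test with one
common dispersion. With per-library counts NB(mean μ, variance μ + φμ²),
the group-1 sum S₁ given the total T = S₁ + S₂ is beta-binomial
BB(T, n₁/φ, n₂/φ), reducing to Binomial(T, n₁/(n₁+n₂)) as φ → 0. Counts
are first rescaled to the geometric-mean effective library size and group
sums rounded to integers. φ is estimated by method of moments pooled over
all non-zero features — Σ(within-group variance − mean) / Σ mean² — and
floored at 0; all-zero features are excluded from estimation and reported
with p = 1. The two-sided p-value sums all conditional outcomes no more
probable than the observed one; with equal group sizes the conditional is
symmetric and the tail sums are computed directly. BH adjustment and
up/down labels at q < 0.05 follow. This replaces a GLM-based pipeline: for
a two-group design with no covariates the conditional exact test is the
textbook analogue and is fully specified, at the cost of tagwise dispersion
shrinkage (a documented deviation).

Calibration is probed on Poisson-null matrices with mean 1000 (4 vs 4,
2000 features): a high-count regime chosen so that the discreteness of the
exact test is negligible — the achievable significance levels near 0.05 are
then spaced by ~0.003, and the measured raw-p rejection rate lands within
3 binomial standard errors of the nominal 0.05 over 20 seeds. At low counts
any exact test is visibly conservative; that is a property of exact
inference, not a calibration defect.

## Repeat-family enrichment

Regions of interest are re-centered to exactly 600 bp. Each region is
assigned to at most one repeat element — the one with the longest base-pair
overlap, ties broken toward the smaller start, then the lexicographically
smaller element name — and at most one family per region is counted.
Background frequencies come from `n_draws = 10` independent length-matched
random placements (averaged), a stabilization of the single background draw
that a one-shot analysis would use. The reported statistic per family is
`log2((obs_count + 0.5) / (mean_bg_count + 0.5))` at equal region numbers;
the 0.5 pseudocount keeps ratios finite when a family is absent from either
side. Enrichment is reported as a descriptive ratio only; no permutation
p-value is attached.

## ATAC peak comparison

Per-sample peak BEDs are union-merged (gap 0) into one peak universe, each
merged peak recording its contributing samples. Differential accessibility
reuses the exact-NB machinery on the peak count matrix (RLE factors
computed on the peaks themselves), labeling peaks at q < 0.05 as
activated- or control-specific by the sign of the fold change. Genomic
feature assignment is midpoint-based with precedence promoter > exon >
intron > intergenic, where the promoter window is −1000/+100 bp around a
transcript 5′ end, strand-aware — the default annotation window of the
common peak-annotation tools. Read-level peak calling is out of scope; the
module starts from peak intervals and counts.

## Single-cell STRT stage

QC keeps cells expressing (count ≥ 1) at least `min_genes` genes; the first
quartile of the genes-per-cell distribution (linear-interpolation quantile)
is reported as the recommended cutoff, matching the practice of dropping
the lowest-quartile cells.

Spike-in normalization downsamples every cell to the minimum spike-in total
over cells: each gene count is binomially thinned at rate
target/spike-total, independently `nresamp = 1000` times, and the per-gene
mean over replicates is returned. This is an explicit specification of
resampling-based spike normalization: expectations equal rate-scaled
counts, and the Monte-Carlo error shrinks as 1/√nresamp (checked against
the binomial oracle).

The rank test standardizes the Wilcoxon rank-sum of the second class per
gene, with a tie-corrected null variance; genes constant across all cells
get statistic 0. The null distribution recomputes all statistics under
`nperms = 1000` seeded label permutations, implemented by permuting the
label vector so that renaming the two classes yields complement subsets and
therefore bit-identical q-values. For a symmetric cutoff t, the plug-in FDR
is the permutation median of #{|stat*| ≥ t} divided by #{|stat| ≥ t}, with
π₀ fixed at 1 (conservative; estimating π₀ would only lower q). A gene's q
is the smallest FDR over cutoffs at which it is called. One behavioral
consequence of the median-based plug-in estimator is that under a global
null the single most extreme gene is exchangeable with the permutation
maxima, so roughly half of null datasets yield one (occasionally two or
three) significant genes; this matches the estimator's standard behavior
and is why the null benchmark tracks calls per seed rather than demanding
exact zero.

## The synthetic-data generator

`cagecraft.synth` emulates the data model of a two-condition (4 + 4
library) regulatory experiment on a 3 × 1 Mb toy genome with 300 genes and
200 enhancers: unidirectional promoter tag pileups (NB mean 20/library,
dispersion 0.3, ±4 bp jitter), balanced divergent enhancer tag pairs (NB
mean 6/side/library, inner gap uniform on [50, 400] bp, 8 bp cluster
spans), Poisson background tags (5×10⁻⁵ /bp/strand/library), a 30% activated
fraction with 4-fold tag increases, one-peak-per-feature ATAC counts (NB
mean 100, dispersion 0.1, 10-fold accessibility changes, activated-only
features closed in control samples), repeat families tiled without overlap
to a 5% genome coverage plus elements planted under 40% of enhancers, and a
12 + 15-cell single-cell experiment (2000 genes, 96 spike-in species,
lognormal depth factors with σ = 0.4 driving both spike totals and gene
means, 100 planted 4-fold DE genes, dispersion 0.3). Planted DE genes are
drawn among genes with baseline mean ≥ 2 counts: a fold change planted on a
never-expressed gene is undetectable by any test, so including such genes
would make the recovery benchmark measure expression level rather than test
power. All randomness flows from one master seed through named substreams,
so each stage regenerates independently and emitted files are
byte-reproducible.

What the generator does **not** emulate: mappability and GC structure, read
sequences and alignment artifacts, multi-modal promoter architecture,
correlated enhancer–promoter activity, overlapping or nested genes, repeat
families with realistic length/divergence distributions, doublets and
ambient contamination in the single-cell stage, or batch effects. Passing
the recovery benchmarks therefore demonstrates the correctness and
calibration of the computations, not their field performance on real
sequencing data.

## Benchmark problem sizes

The acceptance benchmarks use the default generator genome for enhancer
recovery; a 3 × 3 Mb genome with 1000 regions for repeat enrichment (with a
10⁵-draw Monte-Carlo expectation for the planted ratio and a separate
10%-coverage null family over 1000 random regions); 20 seeds × 2000
features for normalization-factor recovery and global-null DE calibration;
and 10 global-null seeds plus one planted benchmark for the single-cell
stage. These sizes keep the full suite within a few minutes on one CPU
while leaving the statistical checks well-powered.

## Known limitations

- Promoter/enhancer counting attributes cluster tags to calls by interval
  overlap with the call span; partially overlapping neighbor clusters are
  counted whole.
- The common-dispersion exact test has no tagwise shrinkage; features with
  atypical dispersion are tested at the pooled value.
- RLE factors inherit the usual composition bias when differential activity
  is strongly asymmetric between conditions (the median feature shifts
  slightly), which can produce a small excess of opposite-direction calls.
- The plug-in FDR's granularity at the extreme tail (discussed above) makes
  single-gene calls under a global null possible.
- `SimConfig` feature placement uses rejection sampling with a minimum
  separation; extremely dense configurations fail with a diagnostic rather
  than degrading.
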