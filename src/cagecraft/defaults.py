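"""Pipeline-wide default constants.

These are the thresholds the pipeline applies throughout: the minimum pooled
tag support for a TSS cluster, the promoter window around annotated transcript
5' ends, the prior count and expression floors for log2-CPM filtering, the
fixed width used when re-centering regions for repeat-family enrichment, the
FDR level for differential calls, and the resampling depths of the single-cell
stage. Functions take these as keyword defaults; changing behaviour for an
analysis means passing an explicit argument, not editing this module.
"""

#: minimum pooled tag support for a TSS cluster to be retained
MIN_CLUSTER_TAGS: int = 3

#: promoter assignment window around a reference transcript 5' end (bp)
PROMOTER_FLANK_BP: int = 300

#: prior count added to raw tag counts before log2-CPM
CPM_PRIOR_COUNT: float = 0.25

#: log2-CPM expression floor for promoters
PROMOTER_LOG2_CPM_FLOOR: float = -2.0

#: log2-CPM expression floor for enhancers (eRNAs are lowly expressed)
ENHANCER_LOG2_CPM_FLOOR: float = -3.5

#: fixed region width for repeat-family enrichment re-centering (bp)
REPEAT_REGION_WIDTH_BP: int = 600

#: BH-adjusted significance level for differential activity calls
DE_FDR_ALPHA: float = 0.05

#: number of binomial resampling replicates in spike-in depth normalization
SPIKE_NRESAMP: int = 1000

#: number of label permutations for the rank-test plug-in FDR
WILCOXON_NPERMS: int = 1000

#: maximum inner gap between divergent TSS clusters paired as an enhancer (bp)
ENHANCER_WINDOW_BP: int = 400

#: calls with |directionality| at or above this are considered unidirectional
MAX_ABS_DIRECTIONALITY: float = 0.8

#: maximum gap between consecutive tag positions joined into one TSS cluster (bp)
TSS_CLUSTER_MAX_GAP_BP: int = 20
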