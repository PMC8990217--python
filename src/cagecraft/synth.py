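"""Seeded synthetic data with planted ground truth.

Emulates the input structure of a two-condition regulatory-genomics
experiment on a small toy genome: unidirectional promoter 5'-tag pileups at
annotated transcript starts, balanced divergent tag pairs at planted
enhancers, genome-wide background tags, replicated two-condition ATAC peak
counts with planted accessibility changes, repeat families tiled at a
configured genome coverage and additionally planted under a fraction of
enhancers, and single-cell negative-binomial counts whose spike-in totals
track each cell's depth factor.

All randomness flows from one master seed through named substreams
(:func:`substream`), so each stage regenerates independently and every output
is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .intervals import ChromSizes, GenomicInterval, RegionSet
from .quantify import CountMatrix
from .repeats import RepeatAnnotation
from .strt import SingleCellCounts
from .tss import TagTrack


def substream(master_seed: int, label: str) -> np.random.Generator:
    """Independent generator for one named stage of the simulation."""
    return np.random.default_rng(
        np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, zlib.crc32(label.encode())])
    )


def _nb_draw(rng: np.random.Generator, mean, dispersion: float, size=None) -> np.ndarray:
    """NB draws parameterized by (mean, dispersion): var = mean + disp * mean^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=size)


@dataclass
class SimConfig:
    """All knobs of the simulation; defaults are the benchmark conditions."""

    chrom_lengths: dict = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000, "chr3": 1_000_000}
    )
    master_seed: int = 0

    # regulatory landscape
    n_promoters: int = 300
    n_enhancers: int = 200
    feature_min_separation: int = 1600
    chrom_margin: int = 2000
    enhancer_gap_range: tuple = (50, 400)
    enhancer_cluster_span: int = 8

    # CAGE/NET-CAGE tag emission (per library)
    n_libraries_per_condition: int = 4
    promoter_tag_mean: float = 20.0
    enhancer_side_tag_mean: float = 6.0
    tag_dispersion: float = 0.3
    promoter_tag_jitter: int = 4
    background_rate_per_bp: float = 5e-5
    activated_fraction: float = 0.3
    cage_fold_change: float = 4.0

    # ATAC peaks
    atac_peak_halfwidth: int = 250
    atac_peak_mean: float = 100.0
    atac_peak_dispersion: float = 0.1
    atac_fold_change: float = 10.0
    atac_peak_jitter: int = 20

    # repeat families: family -> (genome coverage fraction, planted probability
    # under an enhancer, element length)
    repeat_families: dict = field(
        default_factory=lambda: {
            "ERVL-MaLR": {"coverage": 0.05, "planted_prob": 0.4, "element_length": 300},
            "MIR": {"coverage": 0.05, "planted_prob": 0.0, "element_length": 200},
        }
    )

    # single-cell STRT stage (12 vs 15 cells after QC)
    sc_n_cells: tuple = (12, 15)
    sc_n_genes: int = 2000
    sc_n_spikes: int = 96
    sc_base_spike_total: int = 5000
    sc_depth_sigma: float = 0.4
    sc_gene_mean_log_mu: float = 1.0
    sc_gene_mean_log_sigma: float = 1.0
    sc_dispersion: float = 0.3
    sc_n_de_genes: int = 100
    sc_fold_change: float = 4.0
    #: planted DE genes are drawn among genes with baseline mean >= this
    #: (a fold change on a never-expressed gene is undetectable by design)
    sc_de_min_mean: float = 2.0

    def __post_init__(self) -> None:
        self.enhancer_gap_range = tuple(self.enhancer_gap_range)
        self.sc_n_cells = tuple(self.sc_n_cells)
        for fam, spec in self.repeat_families.items():
            if not 0 <= spec["planted_prob"] <= 1:
                raise ValueError(f"planted_prob for {fam} must be in [0,1]")
            if spec["coverage"] <= 0:
                raise ValueError(f"coverage for {fam} must be > 0")
        if not 0 <= self.activated_fraction <= 1:
            raise ValueError("activated_fraction must be in [0,1]")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    @property
    def sizes(self) -> ChromSizes:
        return ChromSizes(self.chrom_lengths)


@dataclass
class GroundTruth:
    """Planted truth serialized alongside the synthetic data."""

    promoters: list  # {gene, chrom, pos, strand, activated}
    enhancers: list  # {id, chrom, start, end, center, gap, activated, planted_repeats}
    repeat_families: dict  # family -> {coverage, planted_prob, n_elements}
    sc_de_genes: dict = field(default_factory=dict)  # gene -> +1 / -1
    master_seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def enhancer_regions(self) -> RegionSet:
        return RegionSet(
            GenomicInterval(e["chrom"], e["start"], e["end"], ".", e["id"])
            for e in self.enhancers
        )


@dataclass
class Landscape:
    sizes: ChromSizes
    five_prime_ends: RegionSet  # 1-bp intervals, name = gene id
    repeats: RepeatAnnotation
    truth: GroundTruth


def _place_features(config: SimConfig, rng: np.random.Generator, n: int) -> list:
    """Non-overlapping feature centers (chrom, pos), rejection-sampled."""
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    placed: dict[str, list[int]] = {c: [] for c in chroms}
    out = []
    max_tries = 200 * n + 1000
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} features with separation "
                f"{config.feature_min_separation} after {max_tries} tries; "
                "reduce feature count or enlarge the genome"
            )
        ci = int(rng.choice(len(chroms), p=weights))
        chrom = chroms[ci]
        lo, hi = config.chrom_margin, int(lengths[ci]) - config.chrom_margin
        pos = int(rng.integers(lo, hi))
        if all(abs(pos - q) >= config.feature_min_separation for q in placed[chrom]):
            placed[chrom].append(pos)
            out.append((chrom, pos))
    return out


def simulate_regulatory_landscape(config: SimConfig) -> Landscape:
    """Place genes, enhancers and repeat elements; return truth alongside."""
    rng = substream(config.master_seed, "landscape")
    sizes = config.sizes
    centers = _place_features(config, rng, config.n_promoters + config.n_enhancers)
    rng.shuffle(centers)

    act_rng = substream(config.master_seed, "activation")
    promoters = []
    for i in range(config.n_promoters):
        chrom, pos = centers[i]
        strand = "+" if act_rng.random() < 0.5 else "-"
        promoters.append(
            {
                "gene": f"gene{i}",
                "chrom": chrom,
                "pos": pos,
                "strand": strand,
                "activated": bool(act_rng.random() < config.activated_fraction),
            }
        )

    gap_lo, gap_hi = config.enhancer_gap_range
    span = config.enhancer_cluster_span
    enhancers = []
    for k in range(config.n_enhancers):
        chrom, c = centers[config.n_promoters + k]
        gap = int(act_rng.integers(gap_lo, gap_hi + 1))
        start = c - gap // 2 - span
        end = c + (gap - gap // 2) + span
        enhancers.append(
            {
                "id": f"enh{k}",
                "chrom": chrom,
                "start": start,
                "end": end,
                "center": c,
                "gap": gap,
                "activated": bool(act_rng.random() < config.activated_fraction),
                "planted_repeats": [],
            }
        )

    # repeat annotation: uniform non-overlapping tiles to the target coverage,
    # plus elements planted under enhancer centers
    rep_rng = substream(config.master_seed, "repeats")
    genome_len = sum(config.chrom_lengths.values())
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in config.chrom_lengths}
    records = []
    chroms = list(config.chrom_lengths)
    lengths = np.array([config.chrom_lengths[c] for c in chroms], dtype=float)
    for family, spec in config.repeat_families.items():
        elem_len = int(spec["element_length"])
        n_elem = int(round(spec["coverage"] * genome_len / elem_len))
        placed = 0
        tries = 0
        while placed < n_elem:
            tries += 1
            if tries > 200 * n_elem:
                raise RuntimeError(f"could not tile family {family} to coverage")
            ci = int(rep_rng.choice(len(chroms), p=lengths / lengths.sum()))
            chrom = chroms[ci]
            start = int(rep_rng.integers(0, int(lengths[ci]) - elem_len))
            if any(start < e and start + elem_len > s for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, start + elem_len))
            records.append(
                (
                    GenomicInterval(chrom, start, start + elem_len),
                    family,
                    f"{family}_tile{placed}",
                )
            )
            placed += 1
        for e in enhancers:
            if rep_rng.random() < spec["planted_prob"]:
                start = e["center"] - elem_len // 2
                records.append(
                    (
                        GenomicInterval(e["chrom"], start, start + elem_len),
                        family,
                        f"{family}_under_{e['id']}",
                    )
                )
                e["planted_repeats"].append(family)

    truth = GroundTruth(
        promoters=promoters,
        enhancers=enhancers,
        repeat_families={
            fam: {
                "coverage": spec["coverage"],
                "planted_prob": spec["planted_prob"],
                "n_elements": sum(1 for _, f, _ in records if f == fam),
            }
            for fam, spec in config.repeat_families.items()
        },
        master_seed=config.master_seed,
    )
    five_prime = RegionSet(
        GenomicInterval(p["chrom"], p["pos"], p["pos"] + 1, p["strand"], p["gene"])
        for p in promoters
    ).sorted()
    return Landscape(sizes, five_prime, RepeatAnnotation(records), truth)


@dataclass
class CageAtacData:
    tracks: list  # list[TagTrack], one per library
    groups: pd.Series  # library -> condition ("control" / "activated")
    atac_sample_peaks: dict  # sample id -> RegionSet
    merged_peak_truth: RegionSet  # one peak per feature, name = feature id
    atac_counts: CountMatrix


def simulate_cage_atac(config: SimConfig, landscape: Landscape) -> CageAtacData:
    """Emit per-library CTSS tag tracks and per-sample ATAC peaks + counts."""
    truth = landscape.truth
    n_per = config.n_libraries_per_condition
    lib_ids = [f"ctrl{i + 1}" for i in range(n_per)] + [f"act{i + 1}" for i in range(n_per)]
    conditions = ["control"] * n_per + ["activated"] * n_per
    groups = pd.Series(conditions, index=lib_ids)

    span = config.enhancer_cluster_span
    tracks = []
    for lib, cond in zip(lib_ids, conditions):
        rng = substream(config.master_seed, f"cage:{lib}")
        rows = []

        for p in truth.promoters:
            mean = config.promoter_tag_mean
            if cond == "activated" and p["activated"]:
                mean *= config.cage_fold_change
            n = int(_nb_draw(rng, mean, config.tag_dispersion))
            if n:
                jit = rng.integers(
                    -config.promoter_tag_jitter, config.promoter_tag_jitter + 1, n
                )
                for pos in p["pos"] + jit:
                    rows.append((p["chrom"], int(pos), p["strand"]))

        for e in truth.enhancers:
            mean = config.enhancer_side_tag_mean
            if cond == "activated" and e["activated"]:
                mean *= config.cage_fold_change
            minus_lo = e["start"]
            plus_lo = e["end"] - span
            for strand, lo in (("-", minus_lo), ("+", plus_lo)):
                n = int(_nb_draw(rng, mean, config.tag_dispersion))
                if n:
                    for pos in rng.integers(lo, lo + span, n):
                        rows.append((e["chrom"], int(pos), strand))

        for chrom, length in config.chrom_lengths.items():
            for strand in ("+", "-"):
                n = int(rng.poisson(config.background_rate_per_bp * length))
                for pos in rng.integers(0, length, n):
                    rows.append((chrom, int(pos), strand))

        df = pd.DataFrame(rows, columns=["chrom", "pos", "strand"])
        df = df.groupby(["chrom", "pos", "strand"], as_index=False).size()
        df = df.rename(columns={"size": "count"}).sort_values(
            ["chrom", "strand", "pos"], ignore_index=True
        )
        tracks.append(TagTrack(lib, df))

    # ATAC: one peak per feature; activated-only features are open (and
    # called as peaks) only in activated samples
    hw = config.atac_peak_halfwidth
    features = [
        (p["gene"], p["chrom"], p["pos"], p["activated"]) for p in truth.promoters
    ] + [(e["id"], e["chrom"], e["center"], e["activated"]) for e in truth.enhancers]
    merged = RegionSet(
        GenomicInterval(chrom, center - hw, center + hw, ".", fid)
        for fid, chrom, center, _ in features
    ).sorted()

    peaks_per_sample: dict[str, RegionSet] = {}
    counts = np.zeros((len(merged), len(lib_ids)), dtype=np.int64)
    atac_rngs = {lib: substream(config.master_seed, f"atac:{lib}") for lib in lib_ids}
    feature_by_id = {fid: (chrom, center, act) for fid, chrom, center, act in features}
    for j, (lib, cond) in enumerate(zip(lib_ids, conditions)):
        rng = atac_rngs[lib]
        sample_peaks = []
        for i, iv in enumerate(merged):
            _, center, activated = feature_by_id[iv.name]
            mean = config.atac_peak_mean
            open_here = cond == "activated" or not activated
            if not open_here:
                mean /= config.atac_fold_change
            counts[i, j] = int(_nb_draw(rng, mean, config.atac_peak_dispersion))
            if open_here:
                jl = int(rng.integers(-config.atac_peak_jitter, config.atac_peak_jitter + 1))
                jr = int(rng.integers(-config.atac_peak_jitter, config.atac_peak_jitter + 1))
                sample_peaks.append(GenomicInterval(iv.chrom, iv.start + jl, iv.end + jr))
        peaks_per_sample[lib] = RegionSet(sample_peaks).sorted()

    cdf = pd.DataFrame(counts, index=[iv.name for iv in merged], columns=lib_ids)
    cm = CountMatrix(cdf, cdf.sum(axis=0).astype(float))
    return CageAtacData(tracks, groups, peaks_per_sample, merged, cm)


def simulate_strt(config: SimConfig) -> tuple[SingleCellCounts, dict]:
    """Single-cell gene + spike-in counts with planted group shifts.

    Each cell has a lognormal depth factor; spike totals are proportional to
    it (the spike-in anchor), and gene counts are NB with mean
    gene_mean x depth x planted fold. Returns the counts and the planted
    gene -> sign map (+1 up in the second group, -1 down).
    """
    rng = substream(config.master_seed, "strt")
    n1, n2 = config.sc_n_cells
    cells = [f"ctrl_c{i + 1}" for i in range(n1)] + [f"kd_c{i + 1}" for i in range(n2)]
    group = pd.Series(["control"] * n1 + ["knockdown"] * n2, index=cells)
    genes = [f"g{i}" for i in range(config.sc_n_genes)]
    spikes = [f"spike{i}" for i in range(config.sc_n_spikes)]

    gene_means = rng.lognormal(
        config.sc_gene_mean_log_mu, config.sc_gene_mean_log_sigma, config.sc_n_genes
    )
    depth = rng.lognormal(0.0, config.sc_depth_sigma, n1 + n2)

    eligible = np.flatnonzero(gene_means >= config.sc_de_min_mean)
    if len(eligible) < config.sc_n_de_genes:
        raise ValueError(
            f"only {len(eligible)} genes reach sc_de_min_mean={config.sc_de_min_mean}; "
            f"cannot plant {config.sc_n_de_genes} DE genes"
        )
    de_idx = rng.choice(eligible, size=config.sc_n_de_genes, replace=False)
    signs = np.where(np.arange(config.sc_n_de_genes) % 2 == 0, 1, -1)
    de_map = {genes[i]: int(s) for i, s in zip(de_idx, signs)}

    fold = np.ones((config.sc_n_genes, n1 + n2))
    in_group2 = np.array([g == "knockdown" for g in group])
    for i, s in zip(de_idx, signs):
        fold[i, in_group2] = config.sc_fold_change if s > 0 else 1.0 / config.sc_fold_change

    mean_mat = gene_means[:, None] * depth[None, :] * fold
    gene_counts = _nb_draw(rng, mean_mat, config.sc_dispersion)

    spike_profile = rng.lognormal(0.0, 1.0, config.sc_n_spikes)
    spike_profile /= spike_profile.sum()
    spike_counts = np.empty((config.sc_n_spikes, n1 + n2), dtype=np.int64)
    for j in range(n1 + n2):
        total = max(1, int(round(config.sc_base_spike_total * depth[j])))
        spike_counts[:, j] = rng.multinomial(total, spike_profile)

    counts = SingleCellCounts(
        pd.DataFrame(gene_counts, index=genes, columns=cells),
        pd.DataFrame(spike_counts, index=spikes, columns=cells),
        group,
    )
    return counts, de_map


def emit(config: SimConfig, outdir: str | Path) -> None:
    """Write every synthetic input in the formats the pipeline reads.

    Produces chrom.sizes, reference 5'-end BED, repeat BED (name =
    family/element), one CTSS TSV per library, per-sample ATAC peak BEDs, the
    ATAC count table, single-cell gene/spike/group tables, the ground-truth
    JSON and the config YAML.
    """
    from .io import write_bed, write_chrom_sizes, write_counts_tsv, write_ctss

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    landscape = simulate_regulatory_landscape(config)
    cage = simulate_cage_atac(config, landscape)
    sc, de_map = simulate_strt(config)
    landscape.truth.sc_de_genes = de_map

    write_chrom_sizes(landscape.sizes, outdir / "genome.chrom.sizes")
    write_bed(landscape.five_prime_ends, outdir / "five_prime_ends.bed")
    rep = landscape.repeats.df
    with open(outdir / "repeats.bed", "w") as fh:
        for row in rep.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.family}/{row.name}\t0\t.\n")
    for track in cage.tracks:
        write_ctss(track.tags, outdir / f"ctss_{track.library_id}.tsv")
    for sample, peaks in cage.atac_sample_peaks.items():
        write_bed(peaks, outdir / f"atac_peaks_{sample}.bed")
    write_counts_tsv(cage.atac_counts.counts, outdir / "atac_counts.tsv")
    write_counts_tsv(sc.genes, outdir / "sc_gene_counts.tsv")
    write_counts_tsv(sc.spikes, outdir / "sc_spike_counts.tsv")
    sc.groups.rename("group").to_csv(outdir / "sc_groups.tsv", sep="\t")
    landscape.truth.to_json(outdir / "ground_truth.json")
    config.to_yaml(outdir / "config.yaml")
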