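"""Readers and writers for the plain-text formats the pipeline consumes:
BED3/BED6, chrom.sizes, CTSS tag tracks and feature-by-library count tables.
All files are tab-separated without headers except count tables, whose header
row carries the library ids.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .intervals import ChromSizes, GenomicInterval, RegionSet


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"])
    return ChromSizes(dict(zip(df["chrom"].astype(str), df["length"])))


def write_chrom_sizes(sizes: ChromSizes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, length in sizes.items():
            fh.write(f"{chrom}\t{length}\n")


def read_bed(path: str | Path) -> RegionSet:
    """Read BED3 or BED6; columns beyond the sixth are ignored."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: BED needs at least 3 columns, got {df.shape[1]}")
    regions = []
    for row in df.itertuples(index=False):
        name = str(row[3]) if df.shape[1] >= 4 and not pd.isna(row[3]) else None
        strand = str(row[5]) if df.shape[1] >= 6 else "."
        regions.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand, name))
    return RegionSet(regions)


def write_bed(
    regions: RegionSet | Sequence[GenomicInterval],
    path: str | Path,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED6 (BED3 when no interval carries name/strand and no scores)."""
    ivs = list(regions)
    six = scores is not None or any(iv.name is not None or iv.strand != "." for iv in ivs)
    with open(path, "w") as fh:
        for i, iv in enumerate(ivs):
            if six:
                score = scores[i] if scores is not None else 0
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_ctss(path: str | Path) -> pd.DataFrame:
    """Read a CTSS track: chrom, 0-based position, strand, tag count."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "pos", "strand", "count"],
        dtype={"chrom": str, "pos": int, "strand": str, "count": int},
    )
    if (df["count"] < 1).any():
        raise ValueError(f"{path}: CTSS counts must be >= 1")
    return df


def write_ctss(tags: pd.DataFrame, path: str | Path) -> None:
    tags.to_csv(path, sep="\t", header=False, index=False, columns=["chrom", "pos", "strand", "count"])


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x libraries count table; header row = library ids."""
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(counts: pd.DataFrame, path: str | Path) -> None:
    counts.to_csv(path, sep="\t")
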