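"""Readers and writers for the plain-text formats the pipeline speaks.

chrom.sizes (two-column TSV), BED3/6, bedGraph, a gene-row GTF subset, and
simple TSV tables (counts, DEGs, orthologs). All coordinates are converted to
0-based half-open at this boundary (GTF is 1-based closed on disk). An
optional BAM adapter is provided behind the same fragment contract when pysam
is installed; BED fragments remain the canonical input.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, InvalidRecordError
from .genome import BinCounts, GenomeLayout, make_bins
from .intervals import IntervalSet

log = logging.getLogger("macrodomains")

__all__ = [
    "read_chrom_sizes",
    "read_bed",
    "write_bed",
    "write_bedgraph",
    "read_bedgraph_counts",
    "read_gene_table",
    "write_gene_table",
    "read_counts_table",
    "read_deg_table",
    "read_ortholog_map",
    "read_fragments_bam",
]

_BED_COLS = ["chrom", "start", "end", "name", "score", "strand"]


def read_chrom_sizes(path, bin_size: int = 2000) -> GenomeLayout:
    """Two-column TSV (name, length) -> :class:`GenomeLayout`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 2:
        raise FormatError(f"{path}: chrom.sizes needs two columns")
    return GenomeLayout(
        [(str(r[0]), int(r[1])) for r in df.itertuples(index=False)],
        bin_size=bin_size,
    )


def read_bed(path, min_cols: int = 3, strict: bool = False) -> pd.DataFrame:
    """Parse a BED3-6 file into a sorted, validated DataFrame.

    Comment/track/browser lines are skipped. Malformed records (start >= end,
    non-numeric coordinates, too few columns) raise in strict mode and are
    dropped with a logged count otherwise.
    """
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    if not first:
        return pd.DataFrame(columns=_BED_COLS[: max(min_cols, 3)])
    width = min(len(first.rstrip("\n").split("\t")), 6)
    if width < min_cols:
        raise FormatError(f"{path}: expected >= {min_cols} BED columns, found {width}")
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str,
        names=_BED_COLS[:width], usecols=range(width), on_bad_lines="skip",
    )
    skip = df["chrom"].str.startswith(("track", "browser")).fillna(False)
    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    bad = (start.isna() | end.isna() | (start < 0) | (start >= end)) & ~skip
    if bad.any():
        if strict:
            i = int(bad.idxmax())
            raise InvalidRecordError(f"{path}: malformed BED record at data row {i}")
        log.warning("%s: dropped %d malformed BED records", path, int(bad.sum()))
    df = df[~bad & ~skip].copy()
    df["start"] = start[~bad & ~skip].astype(np.int64)
    df["end"] = end[~bad & ~skip].astype(np.int64)
    return df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)


def write_bed(intervals, path) -> None:
    """Write intervals (DataFrame, IntervalSet, or (chrom,start,end[,...]) rows)."""
    path = Path(path)
    if isinstance(intervals, IntervalSet):
        intervals = pd.DataFrame(list(intervals), columns=["chrom", "start", "end"])
    elif not isinstance(intervals, pd.DataFrame):
        rows = list(intervals)
        ncol = max((len(r) for r in rows), default=3)
        intervals = pd.DataFrame(rows, columns=_BED_COLS[:ncol])
    cols = [c for c in _BED_COLS if c in intervals.columns]
    intervals.to_csv(path, sep="\t", header=False, index=False, columns=cols)


def write_bedgraph(counts: BinCounts, path) -> None:
    """Export per-bin counts as bedGraph (chrom, start, end, count)."""
    grid = make_bins(counts.layout)
    df = pd.DataFrame(grid, columns=["chrom", "start", "end"])
    df["value"] = counts.counts
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bedgraph_counts(path, layout: GenomeLayout) -> BinCounts:
    """Read a bedGraph written by :func:`write_bedgraph` back onto a layout."""
    df = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"])
    grid = make_bins(layout)
    if len(df) != len(grid):
        raise FormatError(f"{path}: expected {len(grid)} bins, found {len(df)}")
    return BinCounts(layout, df["value"].to_numpy(dtype=np.int64))


def _parse_gtf_attrs(attrs: str) -> dict[str, str]:
    out = {}
    for chunk in attrs.strip().split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        key, _, val = chunk.partition(" ")
        out[key] = val.strip().strip('"')
    return out


def read_gene_table(path, format: str = "tsv", strict: bool = True) -> pd.DataFrame:
    """Load a gene table (one row per gene) from GTF gene rows or 6-column TSV.

    GTF coordinates (1-based closed) are converted to 0-based half-open; the
    TSV format (gene_id, chrom, start, end, strand, biotype) is taken as
    already 0-based half-open. The strand-aware TSS (start for '+',
    end − 1 for '−') is computed here.
    """
    if format == "gtf":
        rows = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                if len(f) < 9 or f[2] != "gene":
                    continue
                attrs = _parse_gtf_attrs(f[8])
                gid = attrs.get("gene_id")
                if not gid:
                    raise InvalidRecordError(f"{path}:{ln}: gene row without gene_id")
                start, end = int(f[3]) - 1, int(f[4])
                rows.append(
                    (gid, f[0], start, end, f[6],
                     attrs.get("gene_biotype", attrs.get("gene_type", "")))
                )
        df = pd.DataFrame(
            rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"]
        )
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        needed = {"gene_id", "chrom", "start", "end", "strand", "biotype"}
        if not needed.issubset(df.columns):
            raise FormatError(f"{path}: gene TSV missing {needed - set(df.columns)}")
    else:
        raise FormatError(f"unknown gene table format {format!r}")

    if (df["start"] >= df["end"]).any():
        raise InvalidRecordError(f"{path}: gene with start >= end")
    dup = df["gene_id"].duplicated()
    if dup.any():
        if strict:
            raise InvalidRecordError(
                f"{path}: duplicate gene_id {df.loc[dup, 'gene_id'].iloc[0]!r}"
            )
        df = df[~dup]
    df = df.reset_index(drop=True)
    df["tss"] = np.where(df["strand"] == "-", df["end"] - 1, df["start"])
    return df


def write_gene_table(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "chrom", "start", "end", "strand", "biotype"]].to_csv(
        path, sep="\t", index=False
    )


def read_counts_table(path) -> pd.DataFrame:
    """TSV (gene_id, count) of raw gene-level fragment counts."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "count"}.issubset(df.columns):
        raise FormatError(f"{path}: counts TSV needs gene_id and count columns")
    if (df["count"] < 0).any():
        raise InvalidRecordError(f"{path}: negative counts")
    return df[["gene_id", "count"]]


def read_deg_table(path) -> pd.DataFrame:
    """TSV (gene_id, log2fc, padj) — a DESeq2-style results table."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "log2fc", "padj"}.issubset(df.columns):
        raise FormatError(f"{path}: DEG TSV needs gene_id, log2fc, padj columns")
    return df[["gene_id", "log2fc", "padj"]]


def read_ortholog_map(path) -> pd.DataFrame:
    """Two-column TSV mapping ids of species A to ids of species B."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs two columns")
    df = df.iloc[:, :2]
    df.columns = ["a", "b"]
    return df


def read_fragments_bam(path, paired: bool = False, min_mapq: int = 0) -> pd.DataFrame:
    """Optional BAM adapter returning the canonical fragment DataFrame.

    For paired data the fragment is the template span (leftmost mate start +
    template length); for single-end data it is the mapped read span, no
    extension. Requires pysam.
    """
    try:
        import pysam
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("BAM input requires the optional pysam dependency") from exc
    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:  # pragma: no cover
        for read in bam:
            if read.is_unmapped or read.mapping_quality < min_mapq:
                continue
            if paired:
                if not read.is_proper_pair or read.template_length <= 0:
                    continue
                start = read.reference_start
                end = start + read.template_length
            else:
                start, end = read.reference_start, read.reference_end
            rows.append((read.reference_name, start, end,
                         "-" if read.is_reverse else "+"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
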