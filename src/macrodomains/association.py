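"""Linking domain dynamics to genes, expression, DEGs, enhancers and orthologs.

The central rule: a protein-coding gene whose body is covered for strictly
more than 80% of its length by mitotic-specific domains is called
*deposition-associated*. The module also computes FPKM, compares expression
between gene groups (Welch's unequal-variance t-test), applies differential
expression thresholds (Padj < 0.01, |log2FC| > 2, both strict), selects
accessible enhancers covered by mitotic-specific domains, and links enhancers
to genes through a closed ±window (default 125 kb) around the TSS.

Gene tables are pandas DataFrames with columns
``gene_id, chrom, start, end, strand, biotype, tss`` (0-based half-open body;
TSS strand-aware: ``start`` for +, ``end - 1`` for −).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .domains import DomainSet
from .errors import FormatError, InvalidParameterError, InvalidRecordError
from .intervals import IntervalSet

__all__ = [
    "EnhancerSet",
    "gene_coverage",
    "deposition_associated_genes",
    "partition_domains_genic",
    "compute_fpkm",
    "compare_expression",
    "filter_degs",
    "deg_overlap",
    "associate_enhancers",
    "link_enhancers_to_genes",
    "intersect_ortholog_sets",
]

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "biotype", "tss"]


@dataclass
class EnhancerSet:
    """Enhancer intervals with per-enhancer accessibility flags."""

    intervals: pd.DataFrame  # columns chrom, start, end (+ optional name)
    accessible: np.ndarray | None = None

    def __post_init__(self):
        self.intervals = self.intervals.reset_index(drop=True)
        if self.accessible is not None:
            self.accessible = np.asarray(self.accessible, dtype=bool)
            if len(self.accessible) != len(self.intervals):
                raise InvalidRecordError("accessible flags do not match enhancers")

    def __len__(self) -> int:
        return len(self.intervals)


def _covered_bp(chrom: str, start: int, end: int, d: IntervalSet) -> int:
    arr = d.chrom_array(chrom)
    if len(arr) == 0:
        return 0
    s = np.minimum(np.maximum(arr[:, 0], start), end)
    e = np.minimum(np.maximum(arr[:, 1], start), end)
    return int((e - s).sum())


def gene_coverage(gene: pd.Series, d: DomainSet | IntervalSet) -> float:
    """Fraction of the gene body covered by the union of the domain set."""
    ivs = d.intervals if isinstance(d, DomainSet) else d
    length = int(gene["end"]) - int(gene["start"])
    if length <= 0:
        raise InvalidRecordError(f"gene {gene.get('gene_id')!r} has non-positive length")
    return _covered_bp(str(gene["chrom"]), int(gene["start"]), int(gene["end"]), ivs) / length


def _coverage_vector(genes: pd.DataFrame, ivs: IntervalSet) -> np.ndarray:
    cov = np.zeros(len(genes))
    for i, (_, g) in enumerate(genes.iterrows()):
        cov[i] = gene_coverage(g, ivs)
    return cov


def deposition_associated_genes(
    genes: pd.DataFrame,
    mitotic_specific: DomainSet,
    threshold: float = 0.8,
) -> pd.DataFrame:
    """Score protein-coding genes against mitotic-specific domains.

    Returns a DataFrame (gene_id, coverage, associated) over protein-coding
    genes; ``associated`` is True when coverage is strictly greater than
    ``threshold`` (default 0.8, i.e. the printed ">80%" rule).
    """
    if not (0 < threshold <= 1):
        raise InvalidParameterError("threshold must be in (0, 1]")
    pc = genes[genes["biotype"] == "protein_coding"].reset_index(drop=True)
    cov = _coverage_vector(pc, mitotic_specific.intervals)
    return pd.DataFrame(
        {
            "gene_id": pc["gene_id"].to_numpy(),
            "coverage": cov,
            "associated": cov > threshold,
        }
    )


def partition_domains_genic(
    d: DomainSet, genes: pd.DataFrame, basis: str = "domain"
) -> tuple[float, float]:
    """Split a domain set into genic vs intergenic proportions.

    ``basis="domain"``: a domain is genic if it overlaps >= 1 bp of any gene
    body; proportions are over the domain count. ``basis="bp"``: base pairs
    inside vs outside the gene-body union, over total domain bp. The two
    proportions sum to 1; an empty set returns (0.0, 0.0).
    """
    if basis not in ("domain", "bp"):
        raise InvalidParameterError(f"basis must be 'domain' or 'bp', got {basis!r}")
    if len(d) == 0:
        return (0.0, 0.0)
    bodies = IntervalSet(
        (str(r.chrom), int(r.start), int(r.end)) for r in genes.itertuples()
    )
    if basis == "domain":
        genic = int(d.intervals.overlaps_any(bodies).sum())
        return (genic / len(d), 1 - genic / len(d))
    inside = d.intervals.intersect(bodies).total_bp()
    total = d.total_bp()
    return (inside / total, 1 - inside / total)


def compute_fpkm(
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    library_size: int | None = None,
) -> pd.DataFrame:
    """FPKM per gene: count / ((body length / 1e3) * (library total / 1e6)).

    ``counts`` has columns (gene_id, count). By default the library total is
    the sum of the supplied counts; pass ``library_size`` when the table is a
    subset of a larger sequencing library (the usual featureCounts situation).
    """
    merged = counts.merge(genes[["gene_id", "start", "end"]], on="gene_id", how="left")
    if merged["start"].isna().any():
        missing = merged.loc[merged["start"].isna(), "gene_id"].tolist()[:5]
        raise FormatError(f"counts for unknown genes, e.g. {missing}")
    length = merged["end"].to_numpy() - merged["start"].to_numpy()
    if (length <= 0).any():
        raise InvalidRecordError("zero-length gene in FPKM computation")
    if (merged["count"].to_numpy() < 0).any():
        raise InvalidRecordError("negative counts")
    total = int(merged["count"].sum()) if library_size is None else int(library_size)
    if total <= 0:
        raise InvalidParameterError("library total must be positive")
    fpkm = merged["count"].to_numpy() / ((length / 1e3) * (total / 1e6))
    return pd.DataFrame(
        {"gene_id": merged["gene_id"], "count": merged["count"], "fpkm": fpkm}
    )


def compare_expression(
    group_a, group_b, log_transform: bool = True
) -> dict:
    """Compare FPKM between two gene groups.

    Reports each group's median FPKM and fraction with FPKM > 1, plus
    Welch's unequal-variance t statistic, Welch–Satterthwaite degrees of
    freedom and two-sided p-value, computed on log2(FPKM + 1) by default
    (``log_transform=False`` uses raw values).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidParameterError("each group needs at least 2 values")
    xa, xb = (np.log2(a + 1), np.log2(b + 1)) if log_transform else (a, b)
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0 and vb == 0:
        t, p = (0.0, 1.0) if xa.mean() == xb.mean() else (np.inf, 0.0)
        df = float(len(a) + len(b) - 2)
    else:
        res = stats.ttest_ind(xa, xb, equal_var=False)
        t, p = float(res.statistic), float(res.pvalue)
        df = float(res.df)
    return {
        "median_a": float(np.median(a)),
        "median_b": float(np.median(b)),
        "frac_gt1_a": float((a > 1).mean()),
        "frac_gt1_b": float((b > 1).mean()),
        "t": t,
        "df": df,
        "pvalue": p,
    }


def filter_degs(
    table: pd.DataFrame, padj_max: float = 0.01, lfc_min: float = 2.0
) -> dict[str, set[str]]:
    """Apply the differential-expression thresholds (both strict).

    Keeps genes with Padj < ``padj_max`` and |log2FC| > ``lfc_min``; returns
    {"up": ids, "down": ids, "all": ids} split by fold-change sign.
    """
    if padj_max <= 0 or lfc_min <= 0:
        raise InvalidParameterError("thresholds must be positive")
    for col in ("gene_id", "log2fc", "padj"):
        if col not in table.columns:
            raise FormatError(f"DEG table missing column {col!r}")
    sig = table[(table["padj"] < padj_max) & (table["log2fc"].abs() > lfc_min)]
    up = set(sig.loc[sig["log2fc"] > 0, "gene_id"])
    down = set(sig.loc[sig["log2fc"] < 0, "gene_id"])
    return {"up": up, "down": down, "all": up | down}


def deg_overlap(
    degs: set[str], associated: set[str], expressed: set[str]
) -> dict:
    """Overlap statistics between DEGs and deposition-associated genes."""
    inter = degs & associated
    return {
        "n_deg": len(degs),
        "n_associated": len(associated),
        "n_overlap": len(inter),
        "frac_of_associated": len(inter) / len(associated) if associated else 0.0,
        "frac_deg_of_expressed": len(degs) / len(expressed) if expressed else 0.0,
        "empty_associated": not associated,
    }


def associate_enhancers(
    enh: EnhancerSet,
    accessibility: IntervalSet,
    mitotic_specific: DomainSet,
    cover_min: float = 0.5,
    mode: str = "fraction",
) -> pd.DataFrame:
    """Select deposition-associated enhancers.

    An enhancer is kept when it (i) overlaps >= 1 bp of an accessibility
    interval and (ii) satisfies the coverage rule against mitotic-specific
    domains: ``mode="fraction"`` (default) requires >= ``cover_min`` of its
    bp covered; ``mode="any"`` requires >= 1 bp; ``mode="full"`` requires
    complete coverage. Returns the enhancer table with ``accessible``,
    ``coverage`` and ``associated`` columns.
    """
    if not (0 < cover_min <= 1):
        raise InvalidParameterError("cover_min must be in (0, 1]")
    if mode not in ("fraction", "any", "full"):
        raise InvalidParameterError(f"unknown coverage mode {mode!r}")
    df = enh.intervals.copy()
    mito = mitotic_specific.intervals
    cov = np.zeros(len(df))
    acc = np.zeros(len(df), dtype=bool)
    for i, r in enumerate(df.itertuples()):
        length = int(r.end) - int(r.start)
        cov[i] = _covered_bp(str(r.chrom), int(r.start), int(r.end), mito) / length
        acc[i] = _covered_bp(str(r.chrom), int(r.start), int(r.end), accessibility) > 0
    if enh.accessible is not None:
        acc &= enh.accessible
    if mode == "any":
        covered = cov > 0
    elif mode == "full":
        covered = cov >= 1.0
    else:
        covered = cov >= cover_min
    df["accessible"] = acc
    df["coverage"] = cov
    df["associated"] = acc & covered
    return df


def link_enhancers_to_genes(
    enhancers: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 125_000,
) -> tuple[pd.DataFrame, float]:
    """Link enhancers to genes within a closed ±window around the TSS.

    An enhancer is linked to a gene when its midpoint lies within
    [TSS − window, TSS + window] on the same chromosome (boundaries
    included); many-to-many links are allowed. Returns the link table
    (enhancer index, gene_id, distance) and the fraction of the supplied
    genes with at least one linked enhancer.
    """
    if window <= 0:
        raise InvalidParameterError("window must be > 0")
    links = []
    linked_genes: set[str] = set()
    for chrom, gsub in genes.groupby("chrom", sort=False):
        esub = enhancers[enhancers["chrom"] == chrom]
        if esub.empty:
            continue
        mids = (esub["start"].to_numpy() + (esub["end"].to_numpy() - esub["start"].to_numpy()) // 2)
        for g in gsub.itertuples():
            dist = np.abs(mids - int(g.tss))
            hit = dist <= window
            if hit.any():
                linked_genes.add(g.gene_id)
                for j, dj in zip(esub.index[hit], dist[hit]):
                    links.append((int(j), g.gene_id, int(dj)))
    link_df = pd.DataFrame(links, columns=["enhancer_index", "gene_id", "distance"])
    frac = len(linked_genes) / len(genes) if len(genes) else 0.0
    return link_df, frac


def intersect_ortholog_sets(
    set_a: set[str],
    set_b: set[str],
    ortholog_map: pd.DataFrame,
    strict: bool = True,
) -> dict:
    """Intersect two gene sets through a one-to-one ortholog map.

    ``ortholog_map`` has columns (a, b). Shared = pairs (a, b) with a in
    set_a, b in set_b and (a, b) in the map; uniques are the complements.
    Duplicate mappings raise a format error in strict mode.
    """
    if list(ortholog_map.columns[:2]) != ["a", "b"]:
        ortholog_map = ortholog_map.rename(
            columns=dict(zip(ortholog_map.columns[:2], ["a", "b"]))
        )
    if strict and (
        ortholog_map["a"].duplicated().any() or ortholog_map["b"].duplicated().any()
    ):
        raise FormatError("ortholog map is not one-to-one")
    pairs = {
        (r.a, r.b)
        for r in ortholog_map.itertuples()
        if r.a in set_a and r.b in set_b
    }
    shared_a = {a for a, _ in pairs}
    shared_b = {b for _, b in pairs}
    return {
        "shared": pairs,
        "a_unique": set_a - shared_a,
        "b_unique": set_b - shared_b,
    }
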