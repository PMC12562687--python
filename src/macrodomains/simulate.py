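"""Seeded synthetic study generator.

Emulates the statistical structure the analysis assumes, at desk scale:

* a multi-chromosome genome (default 2 × 5 Mb, 2 kb bins);
* planted, bin-aligned broad domains in three occupancy classes —
  conserved (both phases), G1/S-specific and mitotic-specific — with
  log-normal lengths (median ≈ 5 kb) and class genome-fractions
  0.30 / 0.10 / 0.15, so planted domains cover a majority (55%) of the
  genome in union while per-phase occupancy stays at 40/45%;
* ChIP fragment midpoints Poisson per bin at a background depth (default 30)
  elevated by ``enrichment_ratio`` (default 5) inside the phase's occupied
  set; input uniform at ``input_depth`` (default 150 — a deep background
  reference, see docs/methods.md);
* genes placed inside mitotic-specific truth (high expression, log-normal
  FPKM median ≈ 8) or elsewhere (median ≈ 0.4), with counts back-computed
  from FPKM against a nominal 20 M-fragment library;
* accessible enhancers inside/outside mitotic-specific truth.

Every generator is a pure function of (params, seed); the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InfeasibleLayoutError, InvalidParameterError
from .domains import DynamicsPartition
from .genome import GenomeLayout
from .intervals import IntervalSet

__all__ = [
    "SimParams",
    "GroundTruth",
    "simulate_truth",
    "simulate_fragments",
    "simulate_genes_expression",
    "simulate_enhancers",
    "simulate_deg_table",
    "simulate_study",
]

_PHASES = {"G1S": 0, "M": 1}
_ROLES = {"chip": 2, "input": 3}


@dataclass
class SimParams:
    """Parameters of the synthetic study (defaults are the study conditions)."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    bin_size: int = 2000
    frac_conserved: float = 0.30
    frac_g1s_specific: float = 0.10
    frac_mitotic_specific: float = 0.15
    domain_median_bp: float = 5000.0  # log-normal median of planted lengths
    domain_sigma: float = 0.6         # log-normal shape (ln scale)
    enrichment_ratio: float = 5.0     # ChIP rate inside occupied loci / background
    depth: float = 30.0               # ChIP background mean midpoints per bin
    input_depth: float = 150.0        # input mean midpoints per bin
    fragment_length: int = 150
    n_genes: int = 300
    covered_gene_fraction: float = 0.5
    gene_max_bins: int = 3
    noncoding_fraction: float = 0.1   # among non-covered genes
    fpkm_high_median: float = 8.0
    fpkm_low_median: float = 0.4
    fpkm_sigma: float = 1.5           # ln-scale sd of both FPKM log-normals
    library_size: int = 20_000_000
    n_enhancers: int = 300
    covered_enhancer_fraction: float = 0.5
    accessible_fraction: float = 0.8
    enhancer_length: int = 600
    seed: int = 0

    def __post_init__(self):
        total = self.frac_conserved + self.frac_g1s_specific + self.frac_mitotic_specific
        if total > 1:
            raise InvalidParameterError(f"class fractions sum to {total} > 1")
        for name in ("enrichment_ratio", "depth", "input_depth"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")
        if self.bin_size <= 0 or self.chrom_length <= 0 or self.n_chroms <= 0:
            raise InvalidParameterError("genome dimensions must be positive")

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            [(f"chr{i + 1}", self.chrom_length) for i in range(self.n_chroms)],
            bin_size=self.bin_size,
        )


@dataclass
class GroundTruth:
    """Planted occupancy classes plus per-feature labels."""

    layout: GenomeLayout
    partition: DynamicsPartition

    def occupied(self, phase: str) -> IntervalSet:
        if phase == "G1S":
            return self.partition.conserved.union(self.partition.g1s_specific)
        if phase == "M":
            return self.partition.conserved.union(self.partition.mitotic_specific)
        raise InvalidParameterError(f"unknown phase {phase!r}")


def _rng(params: SimParams, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(params.seed) % (2**31), *streams])


def _draw_lengths_bins(rng, target_bins: int, params: SimParams) -> list[int]:
    """Log-normal domain lengths (in bins) summing exactly to target_bins."""
    if target_bins <= 0:
        return []
    mu = np.log(max(params.domain_median_bp / params.bin_size, 1.0))
    out, acc = [], 0
    while acc < target_bins:
        l = max(1, int(round(np.exp(rng.normal(mu, params.domain_sigma)))))
        l = min(l, target_bins - acc) if acc + l > target_bins else l
        out.append(l)
        acc += l
    return out


def simulate_truth(params: SimParams) -> GroundTruth:
    """Plant non-overlapping, bin-aligned class domains at the target fractions.

    Per chromosome, class domains are drawn to the per-chromosome bin
    targets, shuffled together, and laid out with multinomially distributed
    gaps, which hits each class fraction to within one domain length.
    """
    layout = params.layout()
    rng = _rng(params, 0)
    B = params.bin_size
    fracs = {
        "conserved": params.frac_conserved,
        "g1s_specific": params.frac_g1s_specific,
        "mitotic_specific": params.frac_mitotic_specific,
    }
    class_ivs: dict[str, list[tuple[str, int, int]]] = {c: [] for c in fracs}
    for chrom, length in layout.chroms:
        n_bins = -(-length // B)
        domains: list[tuple[str, int]] = []
        for cls, f in fracs.items():
            t = int(round(f * n_bins))
            domains.extend((cls, l) for l in _draw_lengths_bins(rng, t, params))
        occupied = sum(l for _, l in domains)
        free = n_bins - occupied
        if free < 0:
            raise InvalidParameterError("class fractions infeasible on this genome")
        order = rng.permutation(len(domains))
        gaps = rng.multinomial(free, np.full(len(domains) + 1, 1.0 / (len(domains) + 1)))
        pos = int(gaps[0])
        for slot, k in enumerate(order):
            cls, l = domains[k]
            start, end = pos * B, min((pos + l) * B, length)
            class_ivs[cls].append((chrom, start, end))
            pos += l + int(gaps[slot + 1])
    conserved = IntervalSet(class_ivs["conserved"])
    g1s = IntervalSet(class_ivs["g1s_specific"])
    mito = IntervalSet(class_ivs["mitotic_specific"])
    unocc = conserved.union(g1s).union(mito).complement(layout.lengths)
    return GroundTruth(layout, DynamicsPartition(conserved, g1s, mito, unocc))


def _enriched_bin_mask(truth: GroundTruth, phase: str) -> np.ndarray:
    layout = truth.layout
    occ = truth.occupied(phase)
    mask = np.zeros(layout.n_bins(), dtype=bool)
    offsets = layout.bin_offsets()
    B = layout.bin_size
    for chrom, s, e in occ:
        b0 = offsets[chrom] + s // B
        b1 = offsets[chrom] + (e - 1) // B
        mask[b0 : b1 + 1] = True
    return mask


def simulate_fragments(
    truth: GroundTruth, phase: str, role: str, params: SimParams
) -> pd.DataFrame:
    """Draw fragments for one (phase, role) sample.

    Per-bin midpoint counts are Poisson: the ChIP rate is ``depth`` in the
    background and ``depth * enrichment_ratio`` inside the phase's occupied
    set; the input rate is ``input_depth`` everywhere. Midpoints are uniform
    within their bin; fragments are ``fragment_length`` bp centred on the
    midpoint (shifted, not truncated, at chromosome edges).
    """
    if phase not in _PHASES:
        raise InvalidParameterError(f"unknown phase {phase!r}")
    if role not in _ROLES:
        raise InvalidParameterError(f"unknown role {role!r}")
    layout = truth.layout
    rng = _rng(params, 1, _PHASES[phase], _ROLES[role])
    if role == "chip":
        mask = _enriched_bin_mask(truth, phase)
        rates = np.where(mask, params.depth * params.enrichment_ratio, params.depth)
    else:
        rates = np.full(layout.n_bins(), params.input_depth)
    counts = rng.poisson(rates)

    B = layout.bin_size
    half = params.fragment_length // 2
    frames = []
    offset = 0
    for chrom, length in layout.chroms:
        nb = -(-length // B)
        c = counts[offset : offset + nb]
        offset += nb
        total = int(c.sum())
        if total == 0:
            continue
        bin_idx = np.repeat(np.arange(nb), c)
        bin_start = bin_idx * B
        bin_width = np.minimum(bin_start + B, length) - bin_start
        mids = bin_start + (rng.random(total) * bin_width).astype(np.int64)
        start = mids - half
        start = np.clip(start, 0, max(length - params.fragment_length, 0))
        end = start + params.fragment_length
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "start": start, "end": end, "strand": "."}
            )
        )
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "strand"])
    return pd.concat(frames, ignore_index=True)


def _place_in_intervals(
    rng, pool: list[tuple[str, int, int]], n: int, min_len: int, max_len_bins: int,
    bin_size: int, aligned: bool,
) -> list[tuple[str, int, int]]:
    """Place n non-overlapping features, one per pooled interval."""
    big = [iv for iv in pool if iv[2] - iv[1] >= min_len]
    if len(big) < n:
        raise InfeasibleLayoutError(
            f"only {len(big)} candidate intervals of >= {min_len} bp for {n} features"
        )
    chosen = rng.choice(len(big), size=n, replace=False)
    placed = []
    for k in chosen:
        chrom, s, e = big[k]
        if aligned:
            nb = (e - s) // bin_size
            fb = int(rng.integers(1, min(max_len_bins, nb) + 1))
            off = int(rng.integers(0, nb - fb + 1))
            placed.append((chrom, s + off * bin_size, s + (off + fb) * bin_size))
        else:
            start = int(rng.integers(s, e - min_len + 1))
            placed.append((chrom, start, start + min_len))
    return placed


def simulate_genes_expression(
    truth: GroundTruth, params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Place genes and draw their expression.

    A ``covered_gene_fraction`` of genes sit fully inside mitotic-specific
    truth domains (bin-aligned, 1..``gene_max_bins`` bins) and draw FPKM from
    the high log-normal; the rest sit in unoccupied / conserved /
    G1/S-specific regions and draw from the low log-normal. Counts are
    back-computed from FPKM, gene length and the nominal library size.

    Returns (gene table, counts table, truth labels).
    """
    rng = _rng(params, 2)
    B = params.bin_size
    n_cov = int(round(params.n_genes * params.covered_gene_fraction))
    n_unc = params.n_genes - n_cov

    mito_pool = list(truth.partition.mitotic_specific)
    covered = _place_in_intervals(
        rng, mito_pool, n_cov, B, params.gene_max_bins, B, aligned=True
    )
    other_pool = (
        list(truth.partition.unoccupied)
        + list(truth.partition.conserved)
        + list(truth.partition.g1s_specific)
    )
    uncovered = _place_in_intervals(
        rng, other_pool, n_unc, B, params.gene_max_bins, B, aligned=True
    )

    rows, labels = [], []
    high_mu, low_mu = np.log(params.fpkm_high_median), np.log(params.fpkm_low_median)
    for i, ((chrom, s, e), cov) in enumerate(
        [(iv, True) for iv in covered] + [(iv, False) for iv in uncovered]
    ):
        gid = f"G{i:05d}"
        strand = "+" if rng.random() < 0.5 else "-"
        tss = s if strand == "+" else e - 1
        noncoding = (not cov) and rng.random() < params.noncoding_fraction
        biotype = "lincRNA" if noncoding else "protein_coding"
        mu = high_mu if cov else low_mu
        fpkm = float(np.exp(rng.normal(mu, params.fpkm_sigma)))
        rows.append((gid, chrom, s, e, strand, biotype, tss, fpkm))
        labels.append((gid, cov, "high" if cov else "low", fpkm))

    genes = pd.DataFrame(
        rows,
        columns=["gene_id", "chrom", "start", "end", "strand", "biotype", "tss", "_fpkm"],
    )
    length_kb = (genes["end"] - genes["start"]) / 1e3
    counts = np.rint(
        genes["_fpkm"] * length_kb * (params.library_size / 1e6)
    ).astype(np.int64)
    counts_df = pd.DataFrame({"gene_id": genes["gene_id"], "count": counts})
    labels_df = pd.DataFrame(
        labels, columns=["gene_id", "covered", "expr_group", "true_fpkm"]
    )
    genes = genes.drop(columns="_fpkm")
    return genes, counts_df, labels_df


def simulate_enhancers(
    truth: GroundTruth, params: SimParams
) -> tuple[pd.DataFrame, IntervalSet, pd.DataFrame]:
    """Place enhancers and accessibility intervals.

    Returns (enhancer table, accessibility interval set, truth labels).
    A ``covered_enhancer_fraction`` of enhancers sit inside mitotic-specific
    truth; ``accessible_fraction`` of all enhancers get an accessibility
    interval (the enhancer ± 200 bp).
    """
    rng = _rng(params, 3)
    n_cov = int(round(params.n_enhancers * params.covered_enhancer_fraction))
    n_out = params.n_enhancers - n_cov
    covered = _place_in_intervals(
        rng, list(truth.partition.mitotic_specific), n_cov,
        params.enhancer_length, 1, params.bin_size, aligned=False,
    )
    outside = _place_in_intervals(
        rng, list(truth.partition.unoccupied), n_out,
        params.enhancer_length, 1, params.bin_size, aligned=False,
    )
    rows, labels, acc = [], [], []
    for i, ((chrom, s, e), cov) in enumerate(
        [(iv, True) for iv in covered] + [(iv, False) for iv in outside]
    ):
        name = f"E{i:04d}"
        accessible = bool(rng.random() < params.accessible_fraction)
        rows.append((chrom, s, e, name))
        labels.append((name, cov, accessible))
        if accessible:
            acc.append((chrom, max(0, s - 200), e + 200))
    enh = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    labels_df = pd.DataFrame(labels, columns=["name", "covered", "accessible"])
    return enh, IntervalSet(acc), labels_df


def simulate_deg_table(
    genes: pd.DataFrame, params: SimParams, deg_fraction: float = 0.1
) -> pd.DataFrame:
    """A synthetic differential-expression table (auxiliary plumbing).

    A ``deg_fraction`` of genes get |log2FC| in (2, 6] with small adjusted p;
    the rest are null. Stands in for an external DESeq2-style results table.
    """
    rng = _rng(params, 4)
    n = len(genes)
    is_deg = rng.random(n) < deg_fraction
    lfc = np.where(
        is_deg,
        rng.uniform(2.0 + 1e-6, 6.0, n) * np.where(rng.random(n) < 0.5, 1, -1),
        rng.normal(0, 0.5, n),
    )
    padj = np.where(is_deg, 10 ** rng.uniform(-8, -3, n), rng.uniform(0.02, 1.0, n))
    return pd.DataFrame(
        {"gene_id": genes["gene_id"], "log2fc": lfc, "padj": padj}
    )


def simulate_study(params: SimParams) -> dict:
    """Run every generator with consistent seeding; returns all pieces."""
    truth = simulate_truth(params)
    frags = {
        (ph, role): simulate_fragments(truth, ph, role, params)
        for ph in _PHASES
        for role in _ROLES
    }
    genes, counts, gene_labels = simulate_genes_expression(truth, params)
    enhancers, accessibility, enh_labels = simulate_enhancers(truth, params)
    degs = simulate_deg_table(genes, params)
    return {
        "params": params,
        "layout": truth.layout,
        "truth": truth,
        "fragments": frags,
        "genes": genes,
        "counts": counts,
        "gene_labels": gene_labels,
        "enhancers": enhancers,
        "accessibility": accessibility,
        "enhancer_labels": enh_labels,
        "degs": degs,
    }
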