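"""End-to-end orchestration: count → call → merge → dynamics → associations.

:func:`run_pipeline` consumes the file-based inputs described by
:class:`RunConfig`, executes every analysis stage, writes BED/TSV artifacts
plus a machine-readable JSON summary, and returns the summary dict. All
numeric defaults mirror the study parameters (2 kb bins, p < 0.05
unadjusted, strict-adjacency merging, >80% gene coverage, ±125 kb enhancer
window) and every one is overridable by flag or YAML.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import association as assoc
from .domains import (
    classify_dynamics,
    domain_stats,
    merge_bins_to_domains,
    shared_fraction,
)
from .enrichment import call_enriched_bins
from .errors import FormatError
from .genome import bin_pearson, count_midpoints, make_bins
from .intervals import IntervalSet
from . import io as mio

log = logging.getLogger("macrodomains")

__all__ = ["RunConfig", "run_pipeline", "write_simulation"]


@dataclass
class RunConfig:
    """Paths and parameters for one pipeline run (defaults = study settings)."""

    chrom_sizes: str = ""
    fragments_g1s_chip: str = ""
    fragments_g1s_input: str = ""
    fragments_m_chip: str = ""
    fragments_m_input: str = ""
    genes: str = ""
    genes_format: str = "tsv"
    counts: str = ""
    library_size: int | None = None
    degs: str = ""
    enhancers: str = ""
    accessibility: str = ""
    outdir: str = "macrodomains_out"
    bin_size: int = 2000
    alpha: float = 0.05
    adjust: str = "none"
    max_gap: int = 0
    coverage_threshold: float = 0.8
    enhancer_window: int = 125_000
    enhancer_cover_min: float = 0.5
    enhancer_mode: str = "fraction"
    genic_basis: str = "domain"
    shared_basis: str = "genome"
    strict: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _read_fragments(path: str) -> pd.DataFrame:
    return mio.read_bed(path, min_cols=3)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts under cfg.outdir."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = mio.read_chrom_sizes(cfg.chrom_sizes, bin_size=cfg.bin_size)
    summary: dict = {
        "parameters": {
            "bin_size": cfg.bin_size,
            "alpha": cfg.alpha,
            "adjust": cfg.adjust,
            "max_gap": cfg.max_gap,
            "coverage_threshold": cfg.coverage_threshold,
            "enhancer_window": cfg.enhancer_window,
            "seed": cfg.seed,
        },
        "genome_length": layout.genome_length,
        "n_bins": layout.n_bins(),
    }

    # --- stage: count ------------------------------------------------------
    frag_paths = {
        ("G1S", "chip"): cfg.fragments_g1s_chip,
        ("G1S", "input"): cfg.fragments_g1s_input,
        ("M", "chip"): cfg.fragments_m_chip,
        ("M", "input"): cfg.fragments_m_input,
    }
    counts = {}
    for (phase, role), path in frag_paths.items():
        frags = _read_fragments(path)
        bc = count_midpoints(frags, layout, strict=cfg.strict)
        counts[(phase, role)] = bc
        mio.write_bedgraph(bc, outdir / f"counts_{phase}_{role}.bedgraph")
        log.info("%s %s: %d fragments", phase, role, bc.total)
        summary[f"library_total_{phase}_{role}"] = bc.total

    summary["pearson_chip_g1s_vs_m"] = bin_pearson(
        counts[("G1S", "chip")], counts[("M", "chip")]
    )

    # --- stage: call + merge ----------------------------------------------
    grid = make_bins(layout)
    domains = {}
    for phase in ("G1S", "M"):
        bins = call_enriched_bins(
            counts[(phase, "chip")], counts[(phase, "input")],
            alpha=cfg.alpha, adjust=cfg.adjust,
        )
        tab = pd.DataFrame(grid, columns=["chrom", "start", "end"])
        tab["chip_k"] = bins.chip_counts
        tab["input_k"] = bins.input_counts
        tab["p"] = bins.pvalues
        tab["significant"] = bins.significant
        tab.to_csv(outdir / f"enriched_bins_{phase}.tsv", sep="\t", index=False)
        mio.write_bed(tab.loc[tab["significant"], ["chrom", "start", "end"]],
                      outdir / f"enriched_bins_{phase}.bed")
        summary[f"n_significant_bins_{phase}"] = bins.n_significant
        d = merge_bins_to_domains(bins, max_gap=cfg.max_gap, condition=phase)
        domains[phase] = d
        mio.write_bed(d.intervals, outdir / f"domains_{phase}.bed")
        st = domain_stats(d, layout)
        summary[f"n_domains_{phase}"] = st.n_domains
        summary[f"median_domain_size_{phase}"] = st.median_size
        summary[f"genome_fraction_{phase}"] = st.genome_fraction

    pd.DataFrame(
        [
            {"condition": ph, **dataclasses.asdict(domain_stats(domains[ph], layout))}
            for ph in ("G1S", "M")
        ]
    ).to_csv(outdir / "domain_stats.tsv", sep="\t", index=False)

    # --- stage: dynamics ---------------------------------------------------
    dyn = classify_dynamics(domains["G1S"], domains["M"], layout)
    rows = []
    for name, ivs in dyn.classes().items():
        mio.write_bed(ivs, outdir / f"dynamics_{name}.bed")
        summary[f"{name}_bp"] = ivs.total_bp()
        summary[f"{name}_genome_fraction"] = ivs.total_bp() / layout.genome_length
        rows.extend((c, s, e, name) for c, s, e in ivs)
    pd.DataFrame(rows, columns=["chrom", "start", "end", "class"]).sort_values(
        ["chrom", "start"], kind="stable"
    ).to_csv(outdir / "dynamics_classes.tsv", sep="\t", index=False)
    summary["tiling_ok"] = dyn.total_bp() == layout.genome_length
    summary["shared_fraction_g1s_m"] = shared_fraction(
        domains["G1S"], domains["M"], layout, basis=cfg.shared_basis
    )

    # --- stage: associations ----------------------------------------------
    if cfg.genes:
        genes = mio.read_gene_table(cfg.genes, format=cfg.genes_format,
                                    strict=cfg.strict)
        genic, intergenic = assoc.partition_domains_genic(
            _as_domainset(dyn.conserved, "conserved"), genes, basis=cfg.genic_basis
        )
        summary["conserved_genic_fraction"] = genic
        summary["conserved_intergenic_fraction"] = intergenic

        scored = assoc.deposition_associated_genes(
            genes, _as_domainset(dyn.mitotic_specific, "mitotic_specific"),
            threshold=cfg.coverage_threshold,
        )
        scored.to_csv(outdir / "associated_genes.tsv", sep="\t", index=False)
        hit_ids = set(scored.loc[scored["associated"], "gene_id"])
        mio.write_bed(
            genes[genes["gene_id"].isin(hit_ids)][
                ["chrom", "start", "end", "gene_id", "tss", "strand"]
            ].rename(columns={"gene_id": "name", "tss": "score"}),
            outdir / "associated_genes.bed",
        )
        summary["n_protein_coding_genes"] = int(len(scored))
        summary["n_associated_genes"] = int(len(hit_ids))

        if cfg.counts:
            counts_tab = mio.read_counts_table(cfg.counts)
            expr = assoc.compute_fpkm(counts_tab, genes,
                                      library_size=cfg.library_size)
            expr.to_csv(outdir / "fpkm.tsv", sep="\t", index=False)
            expr_pc = expr[expr["gene_id"].isin(set(scored["gene_id"]))]
            in_set = expr_pc["gene_id"].isin(hit_ids)
            if in_set.sum() >= 2 and (~in_set).sum() >= 2:
                cmp = assoc.compare_expression(
                    expr_pc.loc[in_set, "fpkm"], expr_pc.loc[~in_set, "fpkm"]
                )
                summary["median_fpkm_associated"] = cmp["median_a"]
                summary["median_fpkm_other"] = cmp["median_b"]
                summary["frac_fpkm_gt1_associated"] = cmp["frac_gt1_a"]
                summary["welch_t"] = cmp["t"]
                summary["welch_p"] = cmp["pvalue"]
            if cfg.degs:
                deg_tab = mio.read_deg_table(cfg.degs)
                deg_sets = assoc.filter_degs(deg_tab)
                expressed = set(expr.loc[expr["fpkm"] > 1, "gene_id"])
                rep = assoc.deg_overlap(deg_sets["all"], hit_ids, expressed)
                summary["n_degs"] = rep["n_deg"]
                summary["n_deg_associated_overlap"] = rep["n_overlap"]
                summary["frac_deg_of_associated"] = rep["frac_of_associated"]

        if cfg.enhancers:
            enh_df = mio.read_bed(cfg.enhancers, min_cols=3, strict=cfg.strict)
            acc = IntervalSet(
                (r.chrom, r.start, r.end)
                for r in mio.read_bed(cfg.accessibility, min_cols=3).itertuples()
            ) if cfg.accessibility else IntervalSet()
            enh_res = assoc.associate_enhancers(
                assoc.EnhancerSet(enh_df), acc,
                _as_domainset(dyn.mitotic_specific, "mitotic_specific"),
                cover_min=cfg.enhancer_cover_min, mode=cfg.enhancer_mode,
            )
            enh_res.to_csv(outdir / "associated_enhancers.tsv", sep="\t", index=False)
            kept = enh_res[enh_res["associated"]]
            mio.write_bed(kept[["chrom", "start", "end"]],
                          outdir / "associated_enhancers.bed")
            summary["n_associated_enhancers"] = int(len(kept))
            assoc_genes = genes[genes["gene_id"].isin(hit_ids)]
            if len(assoc_genes) and len(kept):
                links, frac = assoc.link_enhancers_to_genes(
                    kept.reset_index(drop=True), assoc_genes,
                    window=cfg.enhancer_window,
                )
                links.to_csv(outdir / "enhancer_gene_links.tsv", sep="\t",
                             index=False)
                summary["n_enhancer_gene_links"] = int(len(links))
                summary["frac_associated_genes_with_enhancer"] = frac

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, sort_keys=True, indent=2)
        fh.write("\n")
    return summary


def _as_domainset(ivs: IntervalSet, label: str):
    from .domains import DomainSet

    return DomainSet(label, ivs)


def write_simulation(study: dict, outdir) -> RunConfig:
    """Write a simulated study to disk in the formats the pipeline consumes.

    Returns a ready-to-run :class:`RunConfig` pointing at the written files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    layout = study["layout"]
    params = study["params"]

    with open(outdir / "chrom.sizes", "w") as fh:
        for name, length in layout.chroms:
            fh.write(f"{name}\t{length}\n")

    frag_paths = {}
    for (phase, role), df in study["fragments"].items():
        p = outdir / f"fragments_{phase}_{role}.bed"
        mio.write_bed(df[["chrom", "start", "end"]], p)
        frag_paths[(phase, role)] = str(p)

    mio.write_gene_table(study["genes"], outdir / "genes.tsv")
    study["counts"].to_csv(outdir / "counts.tsv", sep="\t", index=False)
    study["gene_labels"].to_csv(outdir / "gene_labels.tsv", sep="\t", index=False)
    mio.write_bed(study["enhancers"], outdir / "enhancers.bed")
    mio.write_bed(study["accessibility"], outdir / "accessibility.bed")
    study["enhancer_labels"].to_csv(outdir / "enhancer_labels.tsv", sep="\t",
                                    index=False)
    study["degs"].to_csv(outdir / "degs.tsv", sep="\t", index=False)
    for name, ivs in study["truth"].partition.classes().items():
        mio.write_bed(ivs, outdir / f"truth_{name}.bed")
    with open(outdir / "sim_params.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(params), fh, sort_keys=True)

    return RunConfig(
        chrom_sizes=str(outdir / "chrom.sizes"),
        fragments_g1s_chip=frag_paths[("G1S", "chip")],
        fragments_g1s_input=frag_paths[("G1S", "input")],
        fragments_m_chip=frag_paths[("M", "chip")],
        fragments_m_input=frag_paths[("M", "input")],
        genes=str(outdir / "genes.tsv"),
        genes_format="tsv",
        counts=str(outdir / "counts.tsv"),
        library_size=params.library_size,
        degs=str(outdir / "degs.tsv"),
        enhancers=str(outdir / "enhancers.bed"),
        accessibility=str(outdir / "accessibility.bed"),
        outdir=str(outdir / "analysis"),
        bin_size=params.bin_size,
        seed=params.seed,
    )
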