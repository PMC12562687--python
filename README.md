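# macrodomains

Broad histone-variant chromatin-domain calling and cell-cycle dynamics
analysis, with a seeded synthetic-data generator for end-to-end validation.

## The problem

The histone variant macroH2A1 (mH2A1) forms broad chromatin domains that are
dynamically redeposited around mitosis: some loci are occupied throughout the
cell cycle, others gain occupancy specifically in mitosis (deposition) or
lose it after G1/S (removal). Mapping these domains from native ChIP-seq
(ChIP vs input nucleosomal DNA) and relating the mitotic-specific ones to
gene expression and enhancers is the analysis this package implements as a
reusable, tested pipeline — for epigenomics groups who want the published
workflow reproducible on their own fragment data, and testable without any
sequencing download.

## The method

1. **Binning & counting.** The genome is tiled into fixed 2 kb bins; for each
   sample the *midpoint* of every mapped fragment is assigned to exactly one
   bin, giving per-bin counts *k* and a library total *N*.
2. **Enrichment calling.** Each bin is tested with a one-sided Fisher exact
   test on the 2×2 table `[[k_chip, N_chip − k_chip], [k_input, N_input − k_input]]`;
   the p-value is the hypergeometric tail
   P(X ≥ k_chip | margins fixed). Bins with p < 0.05 (unadjusted by default;
   Benjamini–Hochberg optional) are enriched.
3. **Domain assembly.** Maximal runs of adjacent significant bins merge into
   domains (gap tolerance 0 by default).
4. **Dynamics.** Comparing G1/S and mitotic domain sets by base-pair interval
   algebra partitions the genome into conserved (G1S ∩ M), G1/S-specific
   (G1S − M), mitotic-specific (M − G1S) and unoccupied classes; the four
   classes tile the genome exactly.
5. **Association.** Protein-coding genes whose body is >80% covered (strict)
   by mitotic-specific domains are *deposition-associated*; their FPKM
   (count / ((length/10³)·(library/10⁶))) is compared to the remaining genes
   with Welch's t-test on log2(FPKM+1). DEG tables are filtered at
   Padj < 0.01 and |log2FC| > 2 (both strict). Accessible enhancers covered
   by mitotic-specific domains are selected and linked to genes whose TSS
   lies within a closed ±125 kb window of the enhancer midpoint.

## Worked example

Generate the default synthetic study (2 chromosomes × 5 Mb, 2 kb bins,
planted conserved/G1S-specific/mitotic-specific domains covering
30/10/15% of the genome, ChIP enrichment ratio 5 over a background of 30
midpoints per bin) and run the whole pipeline:

```bash
macrodomains simulate --outdir study --seed 1
macrodomains run --config study/run_config.yaml
```

or in Python:

```python
from macrodomains import SimParams, simulate_study, write_simulation, run_pipeline

study = simulate_study(SimParams(seed=1))
cfg = write_simulation(study, "study")
summary = run_pipeline(cfg)
```

Key entries of the printed JSON summary (seed 1):

```
"genome_fraction_G1S": 0.4,          # called domains cover 40% of the genome in G1/S
"genome_fraction_M": 0.4492,         # and 44.9% in mitosis (truth: 40% / 45%)
"conserved_bp": 2996000,             # recovered conserved loci (truth: 3,000,000 bp)
"mitotic_specific_bp": 1496000,      # recovered mitotic deposition (truth: 1,500,000 bp)
"n_domains_G1S": 651,                # merged domains, median size 6 kb
"median_domain_size_M": 6000.0,
"n_associated_genes": 149,           # of 292 protein-coding genes, >80% covered
"median_fpkm_associated": 7.975,     # vs 0.45 for the rest: deposition marks
"median_fpkm_other": 0.45,           #   highly expressed genes
"welch_p": 3.68e-38,
"n_associated_enhancers": 116,       # accessible + >=50% covered
"tiling_ok": true                    # the four dynamics classes tile the genome
```

The 150 genes planted inside mitotic-specific truth are recovered with
sensitivity 0.99 and zero false positives among the 142 genes planted
elsewhere, and every recovered dynamics class matches its planted truth at
base-pair Jaccard ≥ 0.996.

All output files (bedGraph tracks, enriched-bin BED/TSV, domain BEDs,
dynamics class BEDs, association tables, `summary.json`) land in the
configured output directory; every value in the JSON summary can be
recomputed from the emitted BED/TSV artifacts.

## Package layout

| module | contents |
| --- | --- |
| `macrodomains.genome` | genome layout, 2 kb bin grid, fragment-midpoint counting, binned Pearson |
| `macrodomains.intervals` | half-open interval algebra (union/intersect/subtract/complement) |
| `macrodomains.enrichment` | one-sided Fisher bin test, genome-wide calling, BH adjustment |
| `macrodomains.domains` | domain merging, summary stats, dynamics classification, shared fractions |
| `macrodomains.association` | gene coverage, FPKM, Welch comparison, DEG filtering, enhancer linking, ortholog intersection |
| `macrodomains.simulate` | seeded generators for truth, fragments, genes/expression, enhancers |
| `macrodomains.io` | chrom.sizes / BED / bedGraph / GTF / TSV readers and writers, optional BAM adapter |
| `macrodomains.pipeline` | `RunConfig`, end-to-end `run_pipeline`, simulation writer |
| `macrodomains.cli` | `macrodomains` subcommands: simulate, count, call, domains, dynamics, associate, run |

See `docs/methods.md` for the statistical model, parameter defaults and
simulation design.
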