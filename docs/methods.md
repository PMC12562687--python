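# Methods

## Coordinate model and binning

All coordinates are 0-based half-open (BED convention) internally; 1-based
formats (GTF) are converted at the I/O boundary. Each chromosome is tiled
into fixed-width bins (default 2000 bp); the trailing bin may be shorter and
is kept as a first-class bin, so genome-fraction denominators always equal
the true genome length. A fragment contributes the single bin containing its
midpoint, `start + floor(length/2)` — the lower-median position for
even-length fragments, which keeps the map deterministic in integer
arithmetic and strand-independent. Single-end reads are used as their mapped
span with no extension (an optional fixed extension exists but defaults to
off). Binned-track Pearson correlation normalizes each track to counts per
million by default; Pearson r is invariant to this positive scaling, so the
flag only matters for exported tracks.

## Enrichment model

For bin *i* with ChIP count `k_c`, input count `k_i` and library totals
`N_c`, `N_i` (genome-wide midpoint totals, not per-chromosome), the one-sided
Fisher exact p-value is the hypergeometric tail

```
p_i = P(X >= k_c),   X ~ Hypergeom(M = N_c + N_i, successes = N_c, draws = k_c + k_i)
```

computed vectorised via `scipy.stats.hypergeom.sf`, which agrees with exact
integer enumeration to < 1e-15 on all tables with margins ≤ 50 (checked in
the test suite). Only enrichment is tested — depletion of the variant is not
biologically of interest here. A bin is significant when `p < alpha`
(default 0.05, uncorrected; the upstream workflow this mirrors reports
uncorrected p < 0.05). Benjamini–Hochberg adjustment is available behind a
flag; untestable bins (zero counts in both samples) are assigned p = 1, are
never significant, and are excluded from the BH family so they do not dilute
the correction. Monotonicity (larger `k_c` at fixed margins never increases
p) follows from the tail-sum form and is property-tested.

## Domains and dynamics

Significant bins merge into domains as maximal runs of adjacent bins;
`max_gap` (default 0 — "adjacent" read literally as sharing a boundary) can
bridge short unenriched stretches. Abutting intervals always coalesce on
construction so the domain count is well defined, and merging is idempotent.

Dynamics are classified at base-pair resolution by interval algebra, not by
whole-domain identity: conserved = G1S ∩ M, G1/S-specific = G1S − M,
mitotic-specific = M − G1S, unoccupied = genome − (G1S ∪ M). A partially
overlapping domain therefore contributes its overlap to conserved and its
remainder to a specific class. The four classes are mutually disjoint and
tile the genome exactly — an invariant asserted on every pipeline run. The
interval engine itself is a small sorted-array implementation of half-open
union/intersection/subtraction/complement, verified against a per-bp
boolean-mask oracle and against bedtools in the tests.

`shared_fraction` defaults to the genome basis (|a ∩ b| / genome length),
since shared occupancy is conventionally quoted as a portion of the genome;
the union (Jaccard) basis is available as an option.

## Association rules

* **Deposition-associated genes**: protein-coding genes with coverage of the
  gene body by mitotic-specific domains strictly greater than 0.8. The
  strictness matters at the boundary (coverage exactly 0.80 is excluded) and
  is unit-tested. Gene bodies are the annotated TSS-to-TES span, one row per
  gene; isoform resolution is out of scope.
* **FPKM**: `count / ((length/1e3) * (library/1e6))`. The library total
  defaults to the sum of the supplied counts; an explicit `library_size`
  can be given when the count table is a subset of a larger library — which
  is how the simulator uses it, since a desk-scale gene panel cannot carry a
  full transcriptome's worth of fragments.
* **Expression comparison**: Welch's unequal-variance t-test with
  Welch–Satterthwaite degrees of freedom, applied to log2(FPKM + 1) by
  default (raw-FPKM mode available; the transform is a package choice since
  expression is log-normal-ish and heavy-tailed). Medians and the fraction
  of genes with FPKM > 1 are reported alongside.
* **DEG filtering**: Padj < 0.01 and |log2FC| > 2, both strict, applied to a
  supplied results table; differential-expression modeling itself is
  consumed, not implemented.
* **Enhancers**: an enhancer is deposition-associated when it overlaps ≥ 1 bp
  of accessibility intervals and ≥ 50% of its bp is covered by
  mitotic-specific domains. "Covered by" admits several readings; the 50%
  default is a robust middle ground, with `any`/`full` modes exposed.
  Enhancer–gene links use the enhancer midpoint against a *closed*
  ±125 kb window around the TSS (midpoint avoids double-counting long
  enhancers straddling the boundary; a midpoint exactly on the boundary is
  linked).
* **Ortholog intersection** expects a one-to-one map (many-to-many rows must
  be collapsed upstream) and errors on duplicates in strict mode.

## Synthetic study design

The generator plants the structure the analysis assumes, at a scale where
the full pipeline runs in seconds (2 chromosomes × 5 Mb, 2 kb bins = 5000
bins), with every stage a pure function of (params, seed).

**Truth.** Non-overlapping, bin-aligned domains with log-normal lengths
(median 5 kb, ln-sd 0.6) are planted per chromosome to class targets of
30% conserved, 10% G1/S-specific and 15% mitotic-specific — a majority
(55%) of the genome covered in union, conserved the largest class, and
per-phase occupancy of 40% (G1/S) and 45% (M). Placement draws class
domains to the per-chromosome bin quota, shuffles them, and distributes the
free bins as multinomial gaps, which hits each target to within one domain
length (±2% is asserted in tests).

**Fragments.** Per-bin midpoint counts are Poisson — sampling the bin counts
directly matches the statistic under test, rather than simulating reads
against a continuous rate. The ChIP rate is `depth` (30) in the background
and `depth × enrichment_ratio` (150) inside the phase's occupied set; input
is uniform at `input_depth` (150). Midpoints are uniform within the bin;
fragments are 150 bp (mononucleosome scale) centred on the midpoint, which
is irrelevant to the statistics but keeps BED output realistic.

The per-bin Fisher test's power depends strongly on what fraction of the
library falls inside domains: because the ChIP total `N_c` is inflated by
the enriched majority, the per-bin contrast at ratio 5 shrinks as occupancy
grows, and at 60–65% per-phase occupancy a depth-30 library cannot separate
enriched bins from the genome-wide background at p < 0.05 with high
sensitivity. The validation landscape therefore keeps per-phase occupancy at
40–45%, where per-bin sensitivity exceeds 99%, and the input is simulated
5× deeper than the ChIP background so the background reference contributes
negligible sampling noise and the measured error reflects the ChIP counts
the test is about. Real occupancy fractions of 65–80% are reachable with
correspondingly deeper libraries; the generator exposes `depth`,
`input_depth` and the class fractions for such experiments.

**Genes and expression.** Half of the genes (default 300 total) are placed
fully inside mitotic-specific truth domains (bin-aligned, 1–3 bins ≈ 2–6 kb
— compact by real-genome standards, constrained by domain size); the rest
go to unoccupied/conserved/G1/S-specific regions, 10% of them non-coding to
exercise the biotype filter. Covered genes draw FPKM from a log-normal with
median 8, others median 0.4 (ln-sd 1.5 — giving ~90% of the high group
FPKM > 1), mirroring the observed contrast between deposition-associated
and other genes. Counts are back-computed as
`round(FPKM · length_kb · library/1e6)` against a nominal 20 M-fragment
library, so `compute_fpkm` recovers the drawn FPKM to within half-count
rounding (asserted).

**Enhancers.** 300 enhancers of 600 bp, half inside mitotic-specific truth;
80% receive an accessibility interval (enhancer ± 200 bp).

**What the simulation does not model**: mappability, GC bias, copy-number
aberrations (aneuploid cancer genomes), fragment-length variation,
transcript isoforms, and realistic gene lengths. Passing tests demonstrate
the correctness and calibration of the statistical machinery on data obeying
the stated model, not robustness to these real-data artifacts.

## Numerical and degenerate-case choices

* Fisher p-values are clipped to [0, 1]; bins with `k_c = 0` give p = 1
  exactly. At alpha = 1 the strict `p < alpha` rule excludes bins whose tail
  rounds to exactly 1.0 in double precision.
* Zero-variance tracks make Pearson undefined and raise, rather than return
  NaN. Two groups with zero variance and equal means compare as t = 0,
  p = 1 (the no-evidence convention) instead of propagating NaN.
* Empty domain sets report n = 0, median 0 with an `empty` flag, fraction 0.
* Unknown chromosomes in fragment input are dropped with a warning by
  default; `strict` mode raises.
* Midpoint-centred fragments near chromosome edges are shifted inward (not
  truncated) so every emitted fragment has the nominal length; only bins
  within half a fragment of a chromosome end can be perturbed by this.
* Seeds are consumed through `numpy.random.default_rng([seed, stream...])`
  with a distinct stream id per generator and per (phase, role), so samples
  are independent but individually reproducible.

## Problem sizes

The default study (5000 bins, ~2.3 M fragments across four samples, 300
genes, 300 enhancers) runs the full pipeline in roughly ten seconds on one
core; the test suite, including the exhaustive Fisher enumeration
(1.76 M tables) and 100-instance interval-algebra oracles, completes in
under a minute.

## Known limitations

* Domain counts and median sizes are reported per condition from merged
  significant bins; no cross-phase reconciliation of domain identity is
  attempted (loci, not domains, are the unit of dynamics).
* The BH option corrects per genome-wide family of testable bins; no
  hierarchical or spatially aware correction is offered.
* The BAM adapter is a convenience path (template-length midpoints for
  paired data) and is not exercised in the offline test suite; BED fragments
  are the canonical input.
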