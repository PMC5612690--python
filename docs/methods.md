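# Methods

## Statistical model and procedure

### mCpG calling

Each CpG site carries strand-resolved read counts `(C, T)` for the
methylated and unmethylated state. A site is

* **uncovered** when `C + T < min_cov` (default 5) — excluded from every
  sum, *not* treated as unmethylated;
* **methylated** when covered, `C / (C + T) ≥ min_frac` (default 0.10) and
  `C ≥ min_meth_reads` (default 2);
* **unmethylated** otherwise.

The absolute-read floor means a single bisulfite non-conversion or
sequencing error cannot create a methylated site at moderate coverage. The
fraction comparison uses a 1e-9 tolerance so integer ratios that hit the
threshold exactly (e.g. 2/20) are not lost to floating-point rounding.

### Weighted methylation level

For a region with covered CpGs *i = 1..n*:

    level = Σ Cᵢ / Σ (Cᵢ + Tᵢ)

This is the coverage-weighted statistic: deep sites carry more weight, and
raw numerator/denominator sums pool exactly when regions are concatenated
(a mean of per-site fractions would not). `MethylationSummary` keeps the
raw sums precisely so pooling stays exact. A region with no covered CpGs is
flagged "no data" (`level = None`) rather than 0 — callers decide whether
to exclude it.

An optional `zero_uncalled` mode zeroes the numerator contribution of
covered sites that were not called methylated while keeping their coverage
in the denominator; this reproduces a stricter reading in which
sub-threshold methylation is treated as noise. It is off by default, the
plain formula being the community standard.

### Gene- and exon-level calls

A gene body is the span from its first to its last exon. A gene is
**methylated** with ≥ 2 mCpGs in the body (`min_mcpg` configurable); an
exon is **methylated** with ≥ 1 mCpG inside it. The two rules are
deliberately different (gene-level robustness vs exon-level sensitivity)
and both are parameters. Gene-level analyses that depend on a meaningful
level additionally require body level ≥ 0.1 in at least one sample; the
count of genes dropped by this filter is logged in the report funnel.

The gene-body denominator uses covered CpGs only (uncovered CpGs are
unknowable without a genome scan and would bias spans with coverage gaps).

### Genome summary

Per sample: covered-CpG count, mCpG count, and both as fractions of the
**total genomic CpG count** — i.e. `mcpg_ratio` is the share of all
genomic CpGs called methylated, not of the covered subset. Only this
denominator convention makes the two printed percentages of a summary row
mutually consistent, and it is asserted by the acceptance worked example.

### Exon classification and comparisons

Coding exons (CDS features when present, exon features otherwise) of the
representative transcript — most exons, ties broken by longest genomic
span, then lexicographically smallest id — are ranked 5′→3′ in
transcription order; genes with < 3 exons are excluded (counted in the
funnel). An *n*-exon transcript yields exactly 1 first, *n*−2 internal and
1 last exon.

Group contrasts use the Wilcoxon rank-sum (Mann–Whitney U) test: exact
p-values from the full null distribution of U (the standard
count-recursion) when the combined sample is ≤ 20 and untied, otherwise
the tie-corrected normal approximation with continuity correction
(delegated to scipy). Two-sided by default, as the direction was not part
of any hypothesis here. Identical constant samples return p = 1 with a
degeneracy flag. Exon-length and class-level comparisons are restricted to
exons of the methylated gene set.

### Inclusion and boundary profiles

Within genes that are methylated (body level ≥ 0.1) and expressed
(FPKM ≥ 1) in a sample, an exon is **included** when its own FPKM ≥ 1 and
**skipped** otherwise; all other exons are **not evaluable** (with the
count logged). The exon-FPKM operationalization keeps the inclusion call on
the same FPKM ≥ 1 convention as the gene-expression filter; the threshold
is a parameter.

Profiles anchor at the exon's 5′ ("start") and 3′ ("end") boundaries in
transcription orientation, take ±200 bp in 20 bins for internal exons and
±150 bp in 15 bins for first/last (20 bp per bin either way), and pool raw
`C` and `C+T` of covered CpGs per bin across exons; the per-bin level is
the pooled ratio. Pooling is per CpG (count-weighted), not per exon — the
alternative (equal weight per exon) would down-weight CpG-dense exons; the
raw-count choice keeps the per-bin statistic the same weighted level used
everywhere else. Consequences asserted by tests: summed per-bin coverage
equals the window total (each CpG lands in exactly one bin per window);
bins are half-open, so a CpG exactly on the anchor coordinate falls in the
first bin inside the boundary; mirroring all coordinates and strands leaves
profiles unchanged. Exons shorter than the flank contribute only the bins
they genuinely cover; windows are not clipped at the far exon boundary. A
bin with zero pooled coverage is NaN ("no data"), never 0.

### Expression breadth

Breadth = number of samples with FPKM strictly > 1 (the gene/exon
*expressed* filter elsewhere uses ≥ 1; both conventions appear in the
field and both thresholds are parameters). Output is the full breadth
histogram per group plus the fraction expressed in every sample.

## Synthetic data generator

The generator emulates the statistical structure of a two-tissue WGBS +
expression study with known ground truth:

* **Gene layout.** Non-overlapping genes on one linear chromosome,
  random strand, exon count drawn from a distribution over 1–10 with mode
  5 (15% of genes have 1–2 exons and must be excluded downstream), exon
  lengths N(μ_class, 50) floored at 60 bp, introns N(500, 100), 2 kb
  intergenic gaps. CpG sites are scattered at density 0.04/bp.
* **Methylation truth.** Genes are methylated with probability 0.5.
  Within a methylated gene each exon is methylated with a class-dependent
  probability (first 0.55, internal 0.80, last 0.65 — first exons are
  hypomethylated near the transcription start, internal exons most often
  methylated), with at least one methylated exon per methylated gene.
  Methylated exons carry true levels by (class, inclusion): included
  first/internal/last = 0.10/0.30/0.20, skipped internal = 0.10.
  Unmethylated exons and genes sit at the background level 0.002 (the
  bisulfite non-conversion scale). Introns of methylated genes are at
  0.25 so gene-body levels clear the 0.1 filter; flanking sequence within
  200 bp of an exon boundary tracks the exon's own level (methylation
  domains extend past splice sites — this is what makes the
  included-vs-skipped contrast visible across the whole profile window),
  and levels rise by 0.05 within 50 bp of methylated-exon boundaries.
* **Counts.** Coverage ~ max(5, Poisson(20)) per site; methylated reads ~
  beta-binomial(coverage, level, ρ = 0.05). Overdispersion models
  cell-to-cell variability of the methylated state, so it applies only
  where the true level is appreciable (≥ 0.01); background sites stay
  binomial — error reads are independent events. ρ → 0 recovers the
  binomial used by the closed-form checks.
* **Expression.** Two methylation samples; 8 tissue and 11 stage
  expression samples. A gene is expressed per sample with probability 0.95
  (methylated) vs 0.5 (unmethylated); expressed FPKM = 1 + LogNormal(1.5,
  0.7) (always above the threshold), unexpressed ~ U(0, 0.9). Internal
  exons of methylated genes are skipped with probability 0.25; skipped
  exons get FPKM ~ U(0, 0.2) everywhere, included exons inherit the gene's
  FPKM ± 20%. FPKM values are drawn directly rather than simulated from
  reads — expression estimation is upstream of this package's scope.

Identical config + seed gives byte-identical outputs (integer counts,
single `numpy.random.default_rng` stream).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: genomic CpG density variation and CpG islands,
coverage gaps and mapping bias (the coverage floor means every simulated
CpG is covered, so the genome-summary coverage ratio is 100% on synthetic
data), correlated methylation between neighbouring CpGs beyond the shared
regional level, strand asymmetries, isoform diversity (one transcript per
gene), partial inclusion (skipping is all-or-none per exon), and any
dependence structure between expression samples. Recovery results on
synthetic data validate the estimators and the plumbing, not biological
conclusions.

## Problem sizes and numerical choices

The default study size is 2,000 genes (~400k CpG sites, ~10 Mb), the size
used by the analysis scripts and the acceptance script; unit tests use
150–400 genes. Null-behaviour checks run 20 seeded replicates at 400
genes. The rank-sum exact/approximate switchover at combined n = 20
keeps small-sample results bit-for-bit reproducible while the normal
approximation stays within 0.02 of exact p at 8+8 (asserted).

Internal coordinates are 0-based half-open everywhere; GTF/GFF3 (1-based
inclusive) and cytosine-report positions (1-based) are converted at the
I/O boundary only. Strand-resolved CpG counts are kept unmerged: the two
cytosines of a palindromic CpG are independent observations, matching what
Bismark's per-cytosine report emits; merging would halve the nominal site
count and is left to upstream tooling if wanted.

## Known limitations

* Multi-transcript genes are reduced to one representative transcript for
  positional classes; exons unique to minor isoforms are ignored.
* Inclusion calls are threshold-based on exon FPKM, not junction-based;
  genuinely untranscribed 3′ exons of partially expressed genes can be
  labelled skipped.
* The exact rank-sum path requires untied data; tied small samples fall
  back to the normal approximation, whose continuity correction is
  conservative at very small n.
* `genome_summary` needs the total genomic CpG count supplied (the
  simulator records it; for real data it comes from a genome scan, which
  this package does not perform).
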