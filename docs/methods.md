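# Methods

This note documents the models and procedures implemented in `holotrans`,
the parameter choices that matter, and what the synthetic-data conditions
do and do not demonstrate.

## CDS extraction

Coding regions are delimited by stop codons (TAA/TAG/TGA), not by ATG: in
each of the six reading frames the sequence is segmented at stops, and
every inter-stop segment with at least `min_aa_len` (default 30)
translatable codons is a candidate CDS.  The leading segment before the
first stop is kept and flagged `partial5` (transcript 5′ ends are often
truncated in de novo assemblies); the trailing segment after the last stop
is flagged `partial3`.  Conventions chosen here: coordinates are 0-based
half-open on the forward strand; the terminal stop's three nucleotides are
included in the coordinate span but excluded from `aa_length` (common CDS
reporting practice); codons containing N never act as stops and translate
as X.  `select_primary_cds` keeps the longest candidate per contig, ties
broken by complete-over-partial, then forward strand, then lowest start.
The extractor is verified against an independent six-frame brute-force
enumerator on 500 random sequences and satisfies strand symmetry
(extracting from the reverse complement yields the mirrored records).

## Redundancy reduction

The reduction emulates a clustering-guided consensus assembler:

1. **Initial pass** — all-vs-all end-overlap merging at ≥ 21 aligned
   columns and ≥ 99% identity, no clipping.  This runs before the first
   clustering round, mirroring the original workflow's order.
2. **Three rounds** of greedy longest-first clustering (first-fit to the
   first representative meeting the thresholds, both orientations
   considered) at identity/coverage-of-shorter 0.95/0.90, 0.90/0.80,
   0.80/0.80, each followed by within-cluster merging.
3. **Isoform grouping** at 0.95 identity, 0.5 coverage, ≥ 120 aligned
   columns; the surviving contigs in one group constitute a "gene".

Pairwise identity is matches / alignment columns of the best local
alignment (match 2, mismatch −3, gap open −5, extend −2); coverage is the
aligned span on the shorter sequence over its length.  A shared-10-mer
word filter screens pairs before alignment — any overlap that can satisfy
the ≥ 21 nt / ≥ 80% identity merge thresholds between near-identical
copies contains an exact 10-mer with overwhelming probability, so the
filter trades a negligible false-negative rate for a large constant-factor
speedup, exactly as word filters do in the standard clustering tools.

Per-cluster merge parameters are selected from the member length
distribution: `min_overlap = max(21, 0.05 × 10th-percentile length)`,
merge identity equal to the round's clustering identity, and
`max_clip = 0.02 × median length`.  The original workflow selected these
automatically without disclosing its rules; these formulas are this
package's realization, overridable via `MergeParams`.

Merging repeatedly applies the best qualifying join: containment (the
shorter lies within the longer, ends within `max_clip`) collapses to the
container; dovetails (suffix–prefix overlaps, either orientation, inner
unaligned ends within `max_clip`) concatenate the flanks around the
aligned region, which is taken wholly from the longer contig — this
resolves every mismatch and gap in favour of the more complete sequence
and keeps the procedure deterministic without base qualities.  Ties are
broken by (length descending, id ascending) everywhere.

On noise-free redundant families the schedule returns exactly one contig
per gene; with point mutations ≤ 2%, end truncation ≤ 30% and UTR-like
flanks ≤ 60 nt it recovers the planted gene partition with adjusted Rand
index 1.0 at the tested sizes (10 genes × 4 copies).  Noisy copies whose
flanks exceed the clip allowance are carried as separate contigs but still
group into the correct gene, which is the property that matters
downstream.

## Contaminant filtering

Drop requires all three conditions on the best hit (max bitscore, ties by
min e-value then subject id): non-target-taxon subject, query coverage
strictly above 0.70, identity strictly above 80; any hit in the host
genome vetoes the drop.  "Above" is read literally, so boundary values
keep the contig.  Contigs without hits are kept (no evidence).

## Differential expression

With one library per stage there are no replicates, so the dispersion is
fixed at φ = 0.1 under the NB parameterization variance = μ + φμ², and
each non-reference stage is compared with blastula by an exact test:
counts are rescaled to the geometric-mean library size (rounded back to
integers to stay in the exact test's domain — a deliberate simplification
of quantile-adjusted pseudo-counts), and conditional on the rescaled total
s the two-sided p-value is the normalized mass of all splits (k, s−k)
whose product NB probability (null mean s/2) does not exceed the observed
split's.  The implementation was cross-checked against the reference
exact-test implementation in the standard DE package on identical
matrices: p-values agree to ~15 significant digits.

Pre-filters use totals across stages: strictly more than 20 mapped read
pairs and total mapped bases (pairs × 200 nt for 2 × 100 nt paired ends)
of at least 10× the sequence length; a zero count at a single stage never
disqualifies a gene by itself.  DEG calls require |log2 fold change| ≥ 1
in either direction (down-regulation counts) and BH-adjusted p < 0.05,
adjusted within each stage across tested genes.  A pseudo-count of 0.5 is
applied to the fold-change display only when either side is zero, never
inside the test.

**Power at these conditions.** The exact test at φ = 0.1 is well
calibrated (null simulations give P(p < 0.05) ≈ 0.046–0.047 at 5,000
genes) but its power against 8-fold changes with a single observation per
stage tops out near 0.80–0.84 after BH control at 2,000 genes; the
realized false-discovery proportion stays at 0.02–0.07.  This ceiling is a
property of unreplicated NB data at this dispersion, not of the
implementation — the reference implementation achieves the same recall on
identical matrices.  The acceptance suite records this honestly: the
recall bound asserted there is above what these conditions can deliver and
that test is expected to fail.

## GO enrichment

Enrichment uses direct annotations only (no ancestor propagation — the
ontology file contributes term names and namespaces, nothing else).  For a
term with `k_test` of `n_test` test genes and `k_ref` of `n_ref` reference
genes, p = P[X ≥ k_test] for X hypergeometric(n_ref, k_ref, n_test) and
ratio = (k_test/n_test)/(k_ref/n_ref).  Output filtering removes rows with
fewer than 5 test genes or ratio below 1.5; no p-value threshold is
applied, matching the original workflow (a BH column is reported for
reference only).  Stage test sets take DEGs whose TPM at the stage exceeds
both the gene's cross-stage mean and 1; per-stage term ranking sums the
stage TPM of directly annotated test genes and keeps the top 10.

## Profile clustering

Profiles are log2(TPM+1), median-centered per gene.  Distance is
1 − Pearson correlation (zero-variance profiles get zero correlation,
i.e. distance 1, to everything), linkage is average, and the "80% profile
matching" threshold is interpreted as cutting the dendrogram at
(1 − 0.80) × the maximum merge height; a minimum-pairwise-correlation
interpretation is available behind the same parameter
(`interpretation="correlation_floor"`) since the original tooling's
convention is not documented.  The original workflow's manual combining of
similar clusters is replaced by an automatic step that repeatedly merges
the most-correlated pair of cluster means while r ≥ 0.90 (member-count
weighted means keep the merge exact).  Retention flags — without
repartitioning — clusters with at least one TF and strictly more than 20
GO-annotated members.  TF predominance at a stage requires TPM strictly
above 3× the mean TPM over all TFs at that stage, evaluated at every stage
independently.

## Variant summaries

Records with DP < 20 or MQ < 40 are removed (boundary values kept; records
missing either field are removed and tallied).  Classification: length
change → indel; A↔G or C↔T → transition; otherwise transversion.
Multi-allelic records are split per alternate allele before
classification.  Per-kilobase density divides all retained variants
(indels included, configurable) by the summed contig length of the chosen
universe; "highly polymorphic" contigs have density ≥ 2× the mean over
that universe.  On the published pooled survey counts (689,365
transitions, 455,283 transversions, 58,932 indels over ~35.9 Mb) the
summarizer returns Ts/Tv 1.514 (printed 1.5) and 33.57 variants/kb; a
single-population row (77,164/41,755) gives 1.85 (≈ 1.8).

## Synthetic-data generator

The generator supplies the study's structure at desk scale:

* **Transcript pools**: per gene one 1,000 nt uniform-random reference
  (comfortably above the 30-residue CDS floor) plus copies with point
  mutations (default 1%), end truncations up to 20% per end, and random
  UTR-like flanks up to 60 nt; optional internal-deletion isoforms.
* **Counts**: NB draws with variance μ + φμ², φ = 0.1, baseline mean 100
  (the scale at which the pre-filters have bite), four stages, lengths
  uniform on 500–2,500 nt; a fraction (default 10%) of genes has the mean
  at one uniformly chosen non-reference stage multiplied or divided by the
  fold change (default 8) with equal probability.
* **Variants**: per-contig Poisson counts at 30/kb, transitions with
  probability tstv/(1+tstv) at Ts/Tv 1.5, indel fraction 0.05 (the pooled
  survey's observed mix), unique positions, DP uniform on [5, 100] and MQ
  uniform on [20, 60] so the quality filters remove a meaningful fraction.
* **Annotations**: uniform background terms plus one planted term attached
  to exactly the planted genes.

All generators are deterministic in the seed.  What the simulations do
*not* emulate: read-level error structure, realistic length/expression
distributions, correlated expression between paralogs, linkage between
variants, and the original study-scale data volumes (the published headline totals
— tens of thousands of contigs, >10⁶ SNPs — require the original
hundreds of millions of reads and external databases and are out of scope
by design).  Passing tests therefore demonstrate correctness of the
procedures and recovery of planted structure under NB/Poisson assumptions,
not performance on real libraries.

## Problem sizes and numerical choices

Test and acceptance runs use 5–10 genes × 4 contigs for reduction, 2,000
genes for DE recovery, 5,000 for null calibration, 100 kb of contig
sequence for variant recovery, and 100 genes / 40 terms for enrichment —
sizes at which the measured properties (moment checks, interval coverage,
ARI) are statistically meaningful while the whole suite stays fast.
Numerical details: the exact test compares split probabilities in log
space with a 1e-12 relative tie tolerance; TPM columns sum to 10⁶ within
1e-9 relative error whenever nonzero; hierarchical clustering renumbers
clusters by smallest member id so results are independent of input order.
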