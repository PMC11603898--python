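# Methods

This note documents the statistical procedures implemented in `xcimeth`,
the synthetic-data model used to validate them, the defaults and why they
were chosen, and the limitations of both.

## Coordinate and data conventions

All internal coordinates are 0-based half-open; readers shift on ingest
(cytosine reports and GTF are 1-based, BED12 already 0-based).  A CpG
site is identified by the position of its `+` strand cytosine; the
`-` strand partner at the next base is merged into it, so total
methylated/unmethylated counts are conserved by merging and an unpaired
`-` record is simply mapped to its partner position.  CpG dinucleotides
in sequence statistics are attributed to the window or interval
containing their C.

Gene bodies are the span of the longest transcript; promoters are the
2 kb immediately upstream of the body start on the gene's own strand.
Promoters are truncated — never extended — at contig boundaries and
flagged when truncated; records lacking strand cannot define a promoter
and are excluded with a count.  These conventions mean promoter and body
never overlap for the same gene.

## Methylation statistics

Site-level fractional methylation is m/(m+u), defined per sample only at
coverage ≥ `min_coverage` (default 5 reads; a 10-read variant exists to
check robustness of summaries to the cutoff).  Region summaries:

* **weighted**: Σm / Σ(m+u) over all covered sites — each read counts
  once, so deep sites dominate;
* **mean**: the unweighted average of qualifying site fractions,
  reported only when *more than* `min_sites` (default 3) sites qualify.
  The strictly-greater reading of "more than three" is deliberate and
  the threshold is a parameter, since either reading is defensible.

Sex-level summaries pool raw counts across the sex's samples for the
weighted statistic and derive the mean statistic from the pooled counts;
site-level sex comparisons instead average per-sample fractions
(animals as replicates).  Count downsampling is binomial thinning of m
and u independently — expectation-equivalent to read subsampling, and
unbiased for the methylation fraction (the mean absolute fraction change
at 0.5-thinning of 200× sites is ≈ 0.028, exactly what direct binomial
simulation predicts).

## Metagene profiles and expression ranks

Profiles use 2 kb flanks in 100-bp bins and 60 gene-body bins (scaled
per gene); minus-strand genes are reversed so bin 0 is always most
upstream.  Bin values are pooled weighted methylation across genes.
Genes shorter than one bp per body bin are skipped and counted.
Expression rank 0 contains exactly the zero-abundance genes; nonzero
genes are split ascending into 20 equal quantile groups, with
lexicographic gene-id tie-breaking for determinism.  Group abundance for
ranking is the mean across the group's samples.

## Statistical tests

* **Mann–Whitney U**: exact by full enumeration of group assignments
  when n₁+n₂ ≤ 12 (tie-safe, two-sided as the sum of both tails,
  clipped at 1), otherwise the normal approximation with tie correction
  and no continuity correction.
* **Chi-square (2×2)**: Pearson statistic, df = 1, *no* Yates
  correction.  The no-correction choice is substantive: on the
  sex-specific gene counts (479/32302 autosomal vs 14/783 X-linked) it
  gives P = 0.486 while Yates gives 0.58.  The asymptotic P corresponds
  to the permutation mid-P (the test suite verifies this against a
  fixed-margin Monte-Carlo oracle); the plain inclusive permutation P
  is larger on discrete tables.
* **Spearman**: exact two-sided P by enumeration of all n! pairings for
  n ≤ 9, large-sample approximation otherwise; undefined (NaN) on
  constant input.
* **Pearson per-CpG correlation** across samples (default n = 6) uses
  the exact t-based P.  No multiple-testing correction is applied
  anywhere; outputs flag this, matching the raw-P reporting convention
  of the analyses they feed.

## Sex-linkage classification

Per-sex contig depth is the unweighted mean over samples of the
per-sample mean cytosine depth (CG context, per-strand cytosines — the
depth metric operates on cytosines, not merged CpG units).  Eligibility
requires more than 40 cytosines with observed coverage; "informative
cytosine" is read as *covered* cytosine, configurable.  The metric
D = 1 − F̄/M̄ is classified with A-band bounds inclusive and X/Y bounds
strict; the gap (0.5, 0.95] is explicitly unclassified, as is any contig
with zero male depth.  The windowed scan flags `female_absent` windows
(female depth < 0.5 while male ≥ 5) and merges contiguous flags into
exclusion intervals; `PAR_like` windows have |1 − F̄/M̄| < 0.2.  When the
per-cytosine depth is low (e.g. single-digit per-strand coverage), run
the scan on strand-merged counts so the male present-threshold remains
meaningful.

## ASM calling

Reads are summarised to per-read methylation fractions over ≥ 3 CpG
calls in the target region; conflicting duplicate calls are an error.
A locus is ASM when ≥ 90% of reads are extreme **and** both extreme
modes hold ≥ 5 reads.  The extreme cuts default to 0.25/0.75 rather
than 0.1/0.9: with 3–8 CpG calls per read from a ~95%-methylated
allele, a single unconverted-looking call pushes the read fraction to
0.8–0.87, so 0.9 cuts would misclassify a large share of genuinely
single-allele reads (detection collapses to ~16% in simulation), while
0.25/0.75 detects the planted locus in 100% of replicates and still
rejects a both-alleles-50% control in 100%.  Mid-fraction reads from a
non-ASM locus remain far inside the cuts, so the false-call rate is
unaffected.  The region-level site-inclusion rule for delta tracks
(pooled coverage ≥ 2 in either sex) deliberately differs from the
genome-wide ≥ 5-read filter; both are explicit parameters.

## The synthetic-data model

The generator's defaults are the emulated study conditions and are not
tuned per analysis: 3 females vs 3 males; per-allele CpG depth 7.5
(≈ 15× autosomal, ≈ 15×/7.5× female/male X — a typical WGBS depth);
autosomal and male-X methylation centred at 0.75 (mammalian brain
levels) with site sd 0.08; Y-contig methylation 0.30 (hypomethylated,
as unclassified sex-limited sequence is observed to be); female-X
hypomethylation base 0.15, attenuated by 0.002 per promoter CpG so the
effect vanishes near 75 CpGs and flips slightly hypermethylated above
(bounded at −0.05); expression mean 50·exp(−3·promoter methylation)
with lognormal noise sd 0.8, giving a promoter–expression Spearman ρ
around −0.7; 5% of genes carry a planted ±1.5 log2 sex effect and are
labelled significant by the generator (differential-expression calling
itself is out of scope — downstream code only consumes labels); one
Xist-like lncRNA on the X with female-restricted expression and a
600-bp 5' CpG island whose female alleles are methylated at 0.95/0.05
(males 0.95 on their single X).

Coverage is Poisson per allele copy summed over copies (2/2 autosomal,
2/1 X, 0/1 Y), which reproduces the 2:1 female:male X depth and zero
female Y coverage structurally rather than by fiat.  CpG placement is
Bernoulli per position at the configured density after stripping
background CG dinucleotides, so realized density tracks the
specification within a few percent.  ASM reads are 150 bp, single-end,
uniform starts, resampled until they span ≥ 3 in-locus CpGs; each read
draws one allele at random and calls each CpG Bernoulli at that
allele's rate.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: sequencing errors and bisulfite
non-conversion, paired-end structure, non-CpG methylation (CH records
pass through unanalysed), mappability/GC coverage biases, linkage
between neighbouring sites beyond the promoter-level block, and real
annotation complexity (UTRs, overlapping genes, many isoforms).

## Problem sizes

Validation uses desk-scale instances chosen to make the statistical
checks sharp while staying fast: the default genome is ~210 kb with 24
genes; parameter-recovery runs use a 600-kb X (≈ 12,000 CpGs) for delta
recovery, 200 × 6-kb contigs for classifier accuracy, 200 replicates of
60 reads for ASM rates, and 2 × 1.25-Mb contigs with 500 genes for the
correlation-structure checks.  Oracle-equivalence checks run 1000
randomized instances per operation.

## Known limitations

* The pipeline consumes differential-expression tables; it never calls
  differential expression, and DMR calling is likewise out of scope.
* Annotation ingest accepts standard GTF and BED12 only.
* The exact Spearman enumeration is O(n!) and capped at n = 9;  the
  exact Mann–Whitney enumeration is capped at n₁+n₂ = 12.
* The ASM caller phases reads by methylation state only; it does not
  assign reads to named alleles or identify which X is inactive.
* `contig_class_methylation` summarises per-contig means of qualifying
  site fractions; contigs with no qualifying site in a sample simply
  contribute nothing for that sample.
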