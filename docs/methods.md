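# Methods

## Study design the package models

The pipeline targets a pooled comparative RNA-seq design: one susceptible
parental strain and one or more selected phenotypes, each sequenced as a
single RNA pool of many individuals realised as two technical cDNA
libraries. Because biological replication happened at the bench (pooling),
the statistical unit is the library pair, and both analyses — differential
transcription and differential polymorphism — operate on pooled strain-level
counts. All comparisons are selected-versus-parent; direction labels
(over/under) are relative to the susceptible parent.

## Differential transcription

**Quantification.** RPKM = count · 10⁹ / (N · exonic length bp), with N the
library's total retained mapped reads. Strain-level RPKM pools the strain's
counts and library totals, which makes it invariant to how a strain's reads
were split across technical replicates (a tested property).

**Replicate check.** Technical replicates are compared by squared Pearson
correlation of RPKM over genes detected (>0.5 RPKM) in at least one of the
pair; below r² = 0.9 the pipeline warns but proceeds, since pooling is the
design's intent either way. At least 3 genes are required for the
correlation to be defined.

**The count test.** The Audic–Claverie posterior predictive
p(y|x) = C(x+y,y)·N2^y·N1^(x+1)/(N1+N2)^(x+y+1) is evaluated in log space
via log-gamma functions. Tail sums use the negative-binomial CDF identity
P(Y ≤ y) = I_p(x+1, y+1) with p = N1/(N1+N2); the upper tail uses the
complementary form I_{1−p}(y, x+1) rather than 1 − CDF, so tails near 1e-300
are representable — essential when the decision threshold is 1e-15. The
two-sided p doubles the smaller tail, capped at 1 (standard for discrete
two-library tests; a one-sided mode is available). The test is exact but
conservative near the mode because of discreteness, so the null type-I rate
is asserted as ≤ nominal, not equal to it.

**Gates.** Detection: strain RPKM > 0.5 in ≥ 1 strain (the full strain set,
not just the compared pair). BH correction is applied within one comparison
across detected transcripts only, mirroring filter-then-test. A call
requires p_adj < 1e-15 and fold change ≥ 2 in either direction. Fold change
uses floored RPKM, FC = (RPKM_sel + ε)/(RPKM_sus + ε) with ε = 0.05 (one
tenth of the detection threshold), so a transcript silent in one strain
yields a finite, large FC instead of a division by zero.

## Differential polymorphism

**Inputs.** Per-strain pileup allele counts (A/C/G/T per site) with one
site-quality score per strain. Read alignment, base-quality filtering and
the upstream caller's internal confidence score are assumed applied before
the count tables; the quality column is a generic per-site score with a
configurable floor (default permissive).

**Homopolymer mask.** All positions inside single-base runs of ≥ 11 bp
("longer than 10"), plus one flanking position each side. RNA-seq coverage
in such runs is dominated by slippage artefacts.

**SNP calling.** A site must be unmasked, pass the quality floor in every
strain, show ≥ 1 non-reference read, and have > 20 biallelic reads in at
least one strain. The variant allele is the most frequent non-reference
allele summed over strains (alphabetical tie-break); other non-reference
alleles are dropped from denominators, so frequency = var/(ref+var) and
coverage means biallelic coverage. Only substitutions are modelled. A zero
ref+var denominator raises rather than silently reporting 0.

**Differential gate.** For a comparison, Δ = freq_selected − freq_susceptible
in percentage points; the site qualifies when the *summed* coverage of the
two strains is ≥ 30 and |Δ| ≥ 40. The summed (not per-strain-minimum)
reading of total coverage is deliberate: it admits sites where one strain
has coverage as low as ~10 provided the pair is well covered, which matches
how such thresholds behave in practice for pooled data. Both thresholds and
the ≥ operator are configurable. Classification is antisymmetric in the
strain order (Δ flips sign, qualifying status is unchanged) and monotone in
both thresholds — both tested properties.

## Effect annotation

Gene models come from GFF3 (gene/mRNA/exon/CDS/UTR with ID/Parent), stored
0-based half-open internally and converted at I/O. Spliced CDS positions are
1-based in coding orientation; for minus-strand genes they count from the
3'-most genomic CDS base, and codon index = ceil(cds_pos/3). The consequence
of a substitution is computed by splicing the CDS from the genome,
substituting the variant base (complemented for minus strands) and
translating both codons with translation table 1; synonymous means identical
amino acids, stop gains/losses are non-synonymous with '*'. Labels follow
the compact `A847S` convention.

Positions inside a gene but outside CDS/UTR intervals (introns, including
splice sites) are class `other`, as are intergenic positions; an intergenic
SNP within 1 kb (configurable) of a gene is reported with that nearest
gene's id. A SNP overlapping several genes is annotated once per gene and
flagged; the effect-class partition for summaries uses one row per SNP.

The annotator is validated against a brute-force oracle: mutate the genome,
re-extract and translate the whole protein, and diff — agreement on class,
codon index and amino acids is asserted for every synthetic coding SNP on
both strands.

## Enrichment

One-sided Fisher exact tests (hypergeometric upper tail, P(X ≥ a)) compare
each category's share of a selected gene set against the remainder of the
universe (all detected genes by default; configurable). BH correction is
applied across the terms of one selected set; enriched means corrected
p < 0.05. Degenerate margins return p = 1 with a warning. GO terms are
tested flat, without ancestry propagation. The non-synonymous burden test
builds a 2×2 table of qualifying SNPs (candidate vs other genes ×
non-synonymous vs other) and applies the same one-sided test. The same
one-sided Fisher is used for categories and GO terms.

## Synthetic data generator

The generator emulates the design's statistical structure, not its reads:

- **Genome/models:** random contigs; genes with 5'UTR + multi-exon CDS +
  3'UTR on both strands, non-overlapping, CDS always a valid ORF (ATG start,
  no internal stop, stop end, length divisible by 3); a > 10 bp homopolymer
  run placed intergenically and recorded.
- **Counts:** each gene has one rate (expected count per library at the
  nominal 10⁶-read library size); technical replicates share their strain's
  rate; counts are Poisson. Planted differential genes multiply the selected
  strain's rate by 2^log2fc with |log2FC| = 2 by default, and their rates
  are drawn so the lower strain still expects ≥ ~400 reads — the regime in
  which the 1e-15 threshold is reachable and recall is a meaningful
  quantity.
- **Pileups:** per strain and site, coverage ~ Poisson(100) and variant
  count ~ Binomial(coverage, true frequency); defaults plant a 50-point
  frequency difference (0.05 susceptible vs 0.55 selected). Sites are placed
  to cover every genic effect class on both strands plus intergenic sites
  (> 1 kb from genes), one site inside the homopolymer run and one site with
  coverage forced below the detection threshold in every strain. Alleles are
  reported on the forward genome strand. Coding-site effects in the truth
  table are computed from the generator's own transcript bookkeeping,
  independently of the annotation module it is used to test.
- **Categories:** a uniform random gene→category map over ten functional
  categories, so the enrichment stage runs end to end; planted-enrichment
  tests construct their own maps.

What it does **not** model: sequencing error, base quality, mappability,
indels, overdispersion between biological replicates (the design pools
them), multi-isoform genes, overlapping genes, and GC/length biases. Passing
tests therefore demonstrate correctness of the computations under the
design's own assumptions, not robustness to artefacts the design cannot
express.

Determinism: one seed drives separate named substreams (reference, counts,
pileups, categories), so identical configurations yield byte-identical
files.

## Numerical and reporting choices

- Report percentages and frequencies are rounded half-up to one decimal
  (`4.1379 → 4.1`, `4.35… → 4.4`); internal computation is full precision.
- BH adjustment delegates to statsmodels' step-up implementation and is
  tested against a hand-rolled oracle; Fisher tails delegate to scipy's
  hypergeometric survival function and are tested against exact rational
  enumeration.
- p-values of undetected transcripts are computed but not BH-adjusted
  (p_adj is NA and the call is NS).
- Test problem sizes: recall and calibration suites use 200 genes / 40
  planted / 200 sites and 2,000 null genes — large enough for the asserted
  rates to be stable, small enough to run in seconds.

## Known limitations

- The count test assumes shared Poisson rates; with pooled designs any
  biological variance inflates significance, which is why the extreme 1e-15
  threshold is the default. The package does not attempt dispersion
  modelling — with biological replicates, use a negative-binomial GLM tool
  instead.
- Allele frequencies from pooled RNA-seq are expression-weighted; allelic
  imbalance in expression biases them relative to genomic frequencies. The
  estimator here is the plain count ratio.
- One transcript per gene is assumed; with multi-mRNA annotations the first
  transcript is used.
- Adjacent qualifying SNPs (e.g. a dinucleotide substitution) are reported
  as individual records; codon-level interaction between them is not
  modelled.
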