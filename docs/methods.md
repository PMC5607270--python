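# Methods

## Design and model

The analysis targets F1 individuals from reciprocal crosses of two
highly inbred lines. At an *informative locus* — both lines homozygous,
for different alleles — every F1 is heterozygous and each allele's line
(and hence parent) of origin is known. Allelic expression at such a
locus is modelled as binomial sampling of reads from the two alleles:
under the null of balanced expression each read carries either allele
with probability 0.5, so the two-sided exact binomial test of the
allelic counts against 0.5 detects allele-specific expression (ASE).
The two-sided p-value uses the minimum-likelihood construction (the sum
of the probabilities of all outcomes no more probable than the one
observed), the conventional exact two-sided test; it is implemented by
direct enumeration of the Bin(n, 0.5) mass function, vectorised over
loci, and is cross-checked in the tests against an independent
enumeration oracle and `scipy.stats.binomtest`.

Monoallelic expression at a testable locus (one allelic count zero
after error handling) is ASE by definition and receives no p-value.
Biallelic p-values are Benjamini–Hochberg adjusted *within each sample*
over that sample's biallelic testable loci, with an adjusted cutoff of
0.1; monoallelic calls are excluded from the BH family because they
carry no p-value. Replicates are pooled per locus with Fisher's
combined probability test (χ² = −2·Σ ln pᵢ with 2k degrees of freedom)
over the samples that prefer the same allele, requiring at least two
such samples; combined p-values are BH-adjusted across loci within a
tissue at the same 0.1 cutoff. The meta-level adjustment scheme is a
design choice made symmetric with the within-sample rule. A locus whose
qualifying group is entirely monoallelic is declared ASE without a
combined p-value; monoallelic members of a mixed group count as support
but contribute nothing to the Fisher statistic. Ties (equal counts)
define no preferred allele, are never ASE, and are excluded from
preferred-allele grouping. The combined ASE set is the union of
within-sample and meta-analysis calls.

## Filters

Parental DNA calls keep DP > 10 (strict); heterozygous calls whose
minor-allele count is strictly below DP × 1% are reassigned homozygous
for the major allele (sequencing error). The DP × 1% threshold is
compared against total DP as stated, not against the sum of the allelic
depths. Only biallelic SNVs enter the informative set; indels,
multi-allelic records and records on sequences absent from the
reference are dropped (the last with a warning).

RNA observations pass a two-level cascade: site level (cohort-wide),
QD < 2 or FS > 30 removed, and every member of any SNP cluster — three
or more sites whose inclusive span is within 35 bp — removed; then per
observation, DP < 10 or GQ < 30 removed (boundary values kept). Missing
annotations are removed conservatively. Allelic counts strictly below
DP × 1% are zeroed as sequencing error; an observation with both counts
zeroed is unusable.

## Imprinting classification

Classification consumes the within-sample ASE calls, which carry the
per-sample granularity the criterion needs. A gene (per tissue) is
imprinted when at least two distinct samples in each reciprocal cross
have an ASE SNP in the gene and every supporting (sample, SNP) call
prefers the same parental origin; unanimity is enforced across all
supporting pairs, a tied call breaks it, and an opposite-origin call
vetoes the gene (conservative reading of "the same in all samples").
If support is sufficient but the preferred *line* is unanimous instead,
the gene is a line effect. Meta-analysis-only loci do not add support,
since they have no per-sample ASE flag. Mitochondrial genes, maternally
inherited, must classify as maternal-pattern genes and serve as the
positive control; they are reported separately from nuclear genes.

## Dosage compensation

Δ_Z–A = mean log₂ FPKM of Z-linked genes − mean log₂ FPKM of autosomal
genes, per sample, over genes with FPKM strictly above 0.1 (applied per
sample; mean of logs, not log of means). W-linked and mitochondrial
genes belong to neither class. Tissue summaries average per-sample Δ
and report 2^Δ as the Z-to-A ratio. The male-to-female comparison first
normalises samples — "between-sample normalization" is implemented as
scaling each sample so its median autosomal log₂ FPKM (above threshold)
matches the cross-sample median; the `none` option disables it — then
reports 2^(mean log₂ male − mean log₂ female) separately for autosomal
and Z-linked genes.

## Synthetic data

The generator emulates the study design end to end: two inbred parental
lines fixed for different alleles at most loci (with configurable
residual-heterozygosity and shared-allele rates), reciprocal F1 crosses
with 4 samples per direction and two tissues by default, a genome of
five autosomes plus Z and MT with genes laid out along each chromosome
and SNP loci spaced inside genes, and per-locus read depth drawn from a
negative binomial (RNA-seq depth is overdispersed relative to Poisson;
the dispersion is exposed as a knob rather than asserted). Expression
classes are assigned per gene — imprinting and cis regulation act on
genes, and recovery is measured per gene — with imprinted genes drawn
from autosomes only; loci inherit their gene's class. Expected allele
fractions are 0.5 (neutral), `cis_effect` toward the preferred line
(cis), `imprint_effect` toward the allele of the configured parental
origin per cross direction (imprinted), and maternal-only for
mitochondrial loci. Sequencing error flips each read's allele with
probability `error_rate`; on the DNA side an error-contaminated
homozygous call is emitted as heterozygous, giving the DP × 1%
reassignment rule a realistic workload. Parental depths are floored
above the DP filter so the informative set is determined by genotype
structure rather than stochastic depth loss.

Reference bias is modelled as an additive shift (default +0.0098) of
the expected reference-allele fraction in the "original reference"
count table; the N-masked table is emitted without the shift, so
simulated masked ratios sit at ~50% — the small alternative-ward bias
sometimes seen after masking in real data has no stated mechanism and
is not modelled. Quality annotations (QD, FS per site; GQ, DP per
observation) carry a configurable contaminant tail so the filters
remove a known nonzero subset.

The FPKM generator draws per-gene log₂ baselines (normal, sd 1.5
around 3.0) and per-sample lognormal noise; baselines are centred
within each chromosome class so the configured `z_shift` (default
−0.34) is the exact expected Z-minus-autosome difference rather than
being confounded with the random draw of gene means. Female Z
expression sits log₂(`z_male_female_ratio`) (default 1.35) below male;
mitochondrial genes get a high constant baseline. The default cohort is
all male, matching the sequenced design; female samples are generated
only for the dosage analysis.

What the generator does **not** model: reads, alignment artifacts,
fragment/pair structure, splicing and isoforms, beta-binomial
overdispersion of allele fractions, and linkage between loci beyond
shared gene class. Passing tests therefore validate the inference
machinery under the stated sampling model, not robustness to alignment
or isoform artifacts in real data.

## Numerical choices and scale

All randomness flows from a single seed through independent,
order-insensitive substreams per stage; identical configurations give
byte-identical outputs. Zero p-values entering Fisher's method are
clamped to the smallest positive float. BH adjustment is delegated to
`statsmodels` and verified against the textbook definition in the
tests. Coordinates are 1-based VCF-style internally; BED inputs are
converted on read. Pipeline-level simulations in the tests and the
acceptance script use 2,000–20,000 loci over 400–4,000 genes with
negative-binomial depth means of 80–100 — enough for the binomial and
FDR properties under test to be well resolved while keeping runs quick
on one core. Headline counts from the sequenced study (thousands of ASE
SNPs, tens of thousands of testable loci per sample) scale with library
depth and SNP density and are not reproduced at this scale; the
structural results (zero nuclear imprinted genes, maternal
mitochondrial control, balanced parental ratios, partial Z dosage
compensation) are.

## Known limitations

* The binomial caller ignores overdispersion across replicates by
  design; the meta-analysis partially compensates by requiring
  direction-consistent replication.
* Gene assignment maps a SNP to every overlapping gene; with the
  simulated non-overlapping gene layout this is exact, but on real
  annotations overlapping genes double-count support.
* `genotype_consistency` compares genotype labels only; it does not
  model allele dropout at low depth, which in real data inflates
  het→hom disagreement.
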