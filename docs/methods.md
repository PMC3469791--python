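# Methods

## The attribution model

The package's core quantity is the between-population incidence rate ratio
(IRR) attributable to a single biallelic locus. Assumptions:

* genotype frequencies follow Hardy–Weinberg proportions within each
  population (p², 2pq, q² at risk-allele frequency p);
* disease risk depends on the locus through genotypic relative risks
  (GRRs) g₀ = 1, g₁, g₂ for 0/1/2 copies of the risk allele, identical
  across populations;
* populations differ only in allele frequency at the locus (no
  environmental or polygenic differences are modelled).

The normalized incidence rate R(p) = q²g₀ + 2pq·g₁ + p²g₂ is the
population mean relative risk, proportional to incidence under these
assumptions; the IRR for an ordered group pair is R(p_A)/R(p_B).

Case-control studies report per-allele odds ratios, not GRRs. Two mappings
are provided, both setting g₁ = OR:

* `additive_risk` (default): g₂ = 1 + 2(OR − 1) — risk increments add per
  allele copy on the relative-risk scale;
* `multiplicative`: g₂ = OR².

The additive scale is not invariant to which allele is labelled "risk", so
inputs are always oriented first: if OR < 1 the frequencies are
complemented and the OR reciprocated. After orientation the result is
invariant to the input allele labelling (a tested property). Under the
rare-disease approximation the per-allele OR estimates the per-allele risk
ratio, so treating OR as a GRR is adequate for ORs near 1 and overstates
g₂ slightly for large ORs. IRRs are reported at 2 decimal places;
full precision is kept internally.

## Candidate selection

Differences are signed reference-allele frequency differences between a
baseline group and two comparison groups (d_we, d_wa). When both are
nonzero and share a sign, their mean absolute value assigns Highest
(≥ 0.70), High (0.60 to < 0.70) or Moderate (0.40 to < 0.60); lower bounds
closed, upper bounds open. Independently of direction agreement, a SNP
with exactly one absolute difference ≥ 0.70 and the other < 0.40 is
Highest/Low. When a same-direction SNP satisfies both readings the
mean-difference category takes precedence; a zero difference carries no
direction. Category assignment is invariant under relabelling the
reference allele (all differences negate), and is verified exhaustively
against an independent restatement of the rules on a 0.01-step grid.

Thresholds allocate the study-wide α (default 0.05) equally over the four
categories and Bonferroni-divide within each: (α/4)/n. This encodes the
prior that a true signal is equally likely to sit in any category
regardless of category size. Σ(threshold·n) = α over nonempty categories.

## Panel QC

Panel filters run in a fixed order — group availability, then call rate
(default minimum 0.95 in every analysis group), then Hardy–Weinberg
(exact-test p ≥ 1e-7 in every source population) — and each SNP is
attributed to its first failing filter, so the QC report partitions the
input. Pooling of source populations into analysis groups is
count-weighted (summed reference-allele counts over summed chromosome
counts); the pooled record carries the minimum source HWE p, which makes
per-source thresholding order-independent with respect to pooling.
Case-control QC drops samples with call rate < 0.98, then SNPs deviating
from HWE in any control group (p < 1e-5) or with > 5% missing data in any
subject group.

The HWE test is the exact conditional test: given the observed allele
counts, the heterozygote count is enumerated over its support, each
configuration weighted by n!/(n_AA! n_Aa! n_aa!)·2^n_Aa, and the p-value
sums the probabilities of configurations no more probable than the
observed one (two-sided, no mid-p). Log-gamma arithmetic keeps it stable
for large n; it is tested for exact agreement with integer enumeration on
every genotype table up to n = 20.

## Association testing

Per-SNP unconditional logistic regression of case status on minor-allele
dosage plus covariates, fitted by maximum likelihood (statsmodels' Newton
IRLS). Minor-allele status is determined in the combined sample; an exact
0.5 tie keeps the lexicographically smaller allele label. Samples with a
missing dosage are dropped per SNP. Non-convergence and separation
(|log-OR| > 15) are flagged per SNP, never fatal. Wald z statistics give
two-sided p-values; the one-sided p halves the two-sided p when the
estimated direction matches the hypothesized one and is 1 − p/2 otherwise.
The hypothesized direction for each SNP derives from its difference
profile: the baseline-group-enriched allele is expected to be
risk-increasing (equivalently, the comparison-group-enriched allele
protective); the dominant pairwise difference decides which allele that is.

Stratification principal components use the standard genotype-PCA
normalisation: per-SNP mean imputation of missing dosages, centring by
2p̂ and scaling by √(2p̂(1−p̂)), zero-variance SNPs excluded, top-k
left-singular sample loadings (k = 2 by default; the appropriate k is
data-dependent and configurable). Conditional testing adds another SNP's
dosage as a covariate. LD estimation obtains haplotype frequencies from
unphased two-locus genotype tables by EM (the double heterozygote is the
only ambiguous cell), then D′ = |D|/D_max and r² = D²/(p₁q₁p₂q₂).

## Meta-analysis

Fixed-effects inverse-variance pooling on the log-OR scale with weights
1/se²; Cochran's Q with (k − 1) df for heterogeneity. Studies without data
for a SNP are dropped before pooling; a single remaining study passes
through with Q reported as not applicable. When only a printed OR and 95%
CI are available, se = (ln U − ln L)/(2·1.959964). Pooled printed-table
ORs are not expected to round-trip the originals, which were computed from
unrounded per-study estimates.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

* **Frequencies**: Balding–Nichols — ancestral frequency uniform on a
  configurable range (default 0.05–0.95), group frequency
  Beta-distributed with mean p and variance F·p(1−p). F defaults to 0.15
  per group, of the order of continental-scale differentiation and large
  enough that Highest-category differences occur; it is configurable per
  group. Frequencies are stored as pseudo-counts over 200,000 chromosomes
  so the count-based panel TSV round-trips exactly.
* **Genotypes**: binomial HWE draws within groups;
  missing-completely-at-random dropout at a configurable rate (default 0).
* **Disease**: a subject's probability is baseline_risk (default 0.01)
  times the product over planted loci of the GRR of their genotype; risks
  multiply across loci (independent action; a single-locus model is the
  one-element special case). Configurations whose maximum genotype risk
  exceeds 1 are rejected. Cases and controls are sampled from the group
  mixture until the quotas (defaults 692 cases / 3,992 controls, a typical
  discovery-set size; group sizes default to 215/250/257, HapMap-III-scale
  panels) are met. Unplanted SNPs are generated after the disease draw
  from group frequencies, which is distribution-identical because they
  are independent of status.
* One integer seed drives named, deterministically derived sub-streams
  per operation, so every artefact is individually reproducible.

Deliberately not emulated: linkage disequilibrium between simulated loci,
admixed individuals, genotyping batch effects, and non-random missingness.
Tests passing on this generator therefore validate the statistical
machinery under the model's own assumptions — correlated-marker behaviour
(e.g. LD pruning effects on PCA, tag-SNP redundancy at scale) is only
exercised by the dedicated haplotype-structured fixtures, not by the
panel generator.

## Numerical choices

* Exact-test ties are detected with a 1e-12 relative tolerance so
  floating-point noise cannot drop the observed configuration's own
  probability from the tail sum.
* EM for haplotype frequencies: initialized from the unambiguous counts
  with the double heterozygotes split evenly, iterated to a 1e-12
  max-change tolerance (cap 2,000 iterations); checked against direct
  likelihood maximization to 1e-6.
* Logistic fits: maximum 100 Newton iterations; separation flagged at
  |log-OR| > 15; fits that raise are reported as non-converged with NaN
  estimates rather than aborting a batch.
* Thresholds are kept at full precision internally and rendered at 3
  significant figures for reporting.
* Gene annotations are accepted as BED (0-based half-open) and converted
  to 1-based inclusive intervals; the follow-up flank defaults to 5 kb on
  each side.
* The follow-up direction-consistency rule is operationalized as: a gene
  is excluded when any of its follow-up SNPs is significant at the
  discovery cut-off (default two-sided p < 0.01) with its estimated
  effect direction contradicting the hypothesized one. The cut-off is
  configurable; other operationalizations (e.g. majority vote) are
  possible and this choice is deliberately the strictest.

## Test problem sizes

The suite's simulation-based checks use: 1,000 null SNPs at n = 500 for
type-I error; 100 replicates at n = 2,000 + 2,000 for CI coverage of a
planted OR 2.0; 100 seeded end-to-end null runs (20 SNPs, n = 150 + 150)
for family-wise error control, judged against a 3σ Monte-Carlo bound; and
500,000-subject cohorts for simulator-vs-analytic IRR convergence. These
sizes give Monte-Carlo standard errors comfortably below the asserted
tolerances while keeping the full suite fast.

## Known limitations

* The attribution model is single-locus; joint attribution across loci in
  LD would double-count.
* Treating an odds ratio as a GRR is exact only in the rare-disease limit.
* The additive-risk and multiplicative GRR scales diverge for large
  effects (g₂ = 1 + 2(OR − 1) vs OR²); which matches a real locus is an
  empirical question the model cannot settle from a single OR.
* No strand disambiguation for A/T and C/G SNPs, no imputation, no
  liftover, no X-chromosome handling, no random-effects meta-analysis.
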