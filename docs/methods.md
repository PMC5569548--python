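# Methods

## Model and procedure

The association test treats the SNP genotype as the response and the EBV as
the covariate. With `Y_i ∈ {0, ½, 1}` the genotype proportion and `X_i` the
EBV, a logistic link `μ_i = E(Y_i|X_i)` defines the alternative; under the
null slope the mean is a single allele frequency `μ`. The quasi-likelihood
score equations use a working covariance proportional to the numerator
relationship matrix **A**, giving the GLS frequency estimate
`μ̂ = (1'A⁻¹1)⁻¹1'A⁻¹Y` and the score statistic

    W_G = 2/(μ̂(1−μ̂)) · [X'A⁻¹(Y−μ̂1)]² / [X'A⁻¹X − (X'A⁻¹1)(1'A⁻¹1)⁻¹(1'A⁻¹X)],

χ²₁ under the null. The factor 2/(μ̂(1−μ̂)) is the inverse of the variance
of a genotype proportion, `Var(Y) = μ(1−μ)/2` per unit relationship. This
is exactly the right scaling for gene-dropped genotypes: with allele
frequency p, `Cov(Y_i, Y_j) = a_ij · p(1−p)/2`, which is why the null
calibration experiment reproduces χ²₁ without any inflation correction.
The statistic does not account for the genetic variance explained by the
tested marker itself; no adjustment is applied.

Assumptions worth keeping in mind: the EBV enters as a fixed covariate
(its own prediction error and shrinkage are not modelled), the pedigree is
assumed correct, and the working covariance is purely additive-pedigree
(no genomic relationship).

## Numerical and algorithmic choices

- **Kinship.** Full-pedigree A by the tabular method; the analyzed-animal
  submatrix is inverted densely (`numpy.linalg.inv`) after a condition
  check at 1e10 — at a few hundred animals this is exact and cheap. The
  inverse of the *subset* of A is used, not the subset of Henderson's
  sparse full-pedigree inverse; the two differ, and the former is the
  marginal covariance of the analyzed animals. A single unknown parent is
  treated as a unique non-inbred founder.
- **Missing genotypes.** Per-SNP complete-case analysis. Rather than
  re-inverting each observed-animal submatrix, the scan evaluates the five
  quadratic forms that enter W_G through the Schur identity
  `u'(A_oo)⁻¹v = u₀'Wv₀ − (Wu₀)ₘ'W_mm⁻¹(Wv₀)ₘ` with `W = A⁻¹`, which is
  algebraically identical (verified against brute-force re-inversion in
  the tests) and costs one matvec per SNP.
- **Degenerate SNPs.** `μ̂` within 1e-12 of {0, 1} → `monomorphic`;
  denominator M within a 1e-10 relative factor of zero → 
  `degenerate_covariate`. Both are reported statuses, not errors, and such
  rows are excluded from the multiple-testing count m.
- **HWE test.** Exact conditional test (enumeration of heterozygote counts
  given allele counts, two-sided by probability mass), robust at low MAF;
  the 1-df chi-square test is available as a config alternative.
- **QC order.** (1) non-autosomal / unknown-position SNPs out, (2) animals
  below call rate 0.90 out, (3) per-SNP statistics recomputed, (4) SNPs
  filtered by call rate, then MAF, then HWE; a SNP failing several rules is
  counted under the first. "Less than" thresholds carry a 1e-9 guard so
  exact boundary ratios (MAF 10/200, call rate 90/100) are retained despite
  float rounding. MAF and call rates use non-missing calls only; accepted
  autosome labels default to the bovine 1–29 and are configurable.
- **FDR.** Standard BH step-up (via statsmodels), boundary case
  `P(i) = i·q/m` rejected — immaterial for continuous p-values. Scopes:
  genome-wide (m = all tested SNPs) and per-chromosome. Bonferroni is
  `p ≤ α/m`.
- **LD.** Two-locus EM from unphased genotypes, initialized at linkage
  equilibrium, tolerance 1e-9 on frequencies, ≤1000 iterations, with a
  monotone log-likelihood assertion. Only the double-heterozygote class is
  phase-ambiguous, so allele margins are fixed at their sample values and
  EM is effectively one-dimensional. Per-chromosome summaries average the
  defined upper-triangle pairs; undefined pairs (fixed margins) are counted
  but never imputed as zero.
- **Annotation.** Gene spans are 1-based inclusive; distance is the gap to
  the nearest span edge, reported in kb rounded to 2 decimals (Python
  decimal rounding, not numpy's scaled rounding, which differs at
  near-ties). Equidistant genes are all reported. Subtypes (exon, 5′/3′
  UTR, intron) require sub-features in the GFF3; without them intragenic
  hits stay "intragenic". Direction is strand-relative: a SNP off the 5′
  end is upstream. The nearest-gene search is unbounded.

## The synthetic cohort

The generator emulates the data-generating process the analysis assumes,
at the design scale of a single-generation half-sib study: 49 founder
sires, 355 founder dams, 399 genotyped calves (sires drawn uniformly per
calf → half-sib families of mean size ~8; dams used round-robin, hence
mostly once). Defaults: 5 chromosomes × 200 SNPs at 50 kb spacing, LD
blocks of 10 SNPs, founder haplotypes drawn from a pool of 8 ancestral
haplotypes per block (Dirichlet(1.5) pool weights, 2% copy-error rate),
target minor allele frequencies uniform on [0.05, 0.5], 2% missing calls.
The pool-mixture construction makes true allele and two-locus haplotype
frequencies available in closed form, so true within-block r² is recorded
in a truth table rather than estimated.

Traits are simulated as EBV-like values: optional causal SNP effects
(default, when enabled, drawn among SNPs with true MAF ≥ 0.10 — a rare
causal allele is undetectable at n ≈ 400 and would make power experiments
meaningless) plus a polygenic value generated by the pedigree recursion
(child = mid-parent + Mendelian deviation with variance
σ²ₐ(0.5 − 0.25(F_s + F_d))), so its covariance is exactly σ²ₐA, plus
independent residual noise. Defaults σ²ₐ = σ²ₑ = 0.5 correspond to an EBV
reliability of about one half, typical of young animals evaluated mostly on
parent and progeny information. What the generator does *not* model:
coalescent-accurate LD decay, selection and assortative mating, genotyping
error beyond missingness, and the REML shrinkage structure of real EBVs —
so passing tests demonstrate the statistical machinery is correct under its
own assumptions, not that real Canchim-scale data would reproduce any
specific count of associations.

## Validation experiment design

Problem sizes are desk-scale choices: exactness and invariance checks use
random pedigrees of up to 30 animals (100 and 1,000 cases); kinship algebra
uses 100 random pedigrees up to n = 200; null calibration gene-drops 10,000
SNPs through the default 803-animal pedigree — *without* LD blocks, since
the KS comparison against χ²₁ treats per-SNP statistics as independent
draws, which within-block LD violates (type-I error is insensitive to this,
the KS p-value is not); LD recovery uses 2 × 100 SNPs (900 within-block
pairs) and is judged by mean absolute error ≤ 0.05 — with 400 *related*
animals the sampling error of a single r² estimate can reach ~0.2, so a
per-pair band at 0.05 is not attainable by any estimator at this design;
power uses 50 replicates of a 500-SNP scan with one causal SNP at half a
residual SD per allele copy, asking that it rank first and carry the
suggestive (chromosome-wise FDR 10%) flag in the majority of replicates.

## Known limitations

- Single continuous covariate only; no multi-trait or multi-locus models.
- Dense kinship algebra targets hundreds-to-thousands of animals, not
  national evaluations.
- The EM r² estimator assumes random mating within the analyzed set; in a
  structured cohort it inherits the usual bias of pooled estimates.
- GFF3 parsing expects `gene` features; transcript-level consequence
  calling (e.g. splice-site classes) is out of scope.
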