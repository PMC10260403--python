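# Methods

This note documents the statistical model behind `cogexome`, the defaults
and units of every user-facing parameter, the scope of the synthetic
cohort generator, and the numerical choices that are not obvious from the
code.

## 1. Problem setting

Large exome-sequencing studies test whether the *burden* of ultrarare
coding variants in a gene (or gene set, or the whole exome) associates
with a phenotype. Because qualifying variants are individually too rare
to test, the per-sample cumulative minor-allele count over qualifying
variants is used as a single regressor. The pipeline covers:

1. variant QC and functional classification,
2. burden construction at exome-wide / gene-set / per-gene granularity,
3. phenotype preparation (covariates, rank-INT, residualization),
4. a two-step whole-genome regression (WGR) that absorbs polygenic
   background and relatedness through leave-one-chromosome-out (LOCO)
   offsets,
5. association tests (linear, logistic, Firth) with multiplicity control
   and genomic-inflation diagnostics,
6. random-effects meta-analysis across cohorts,
7. a phenome-wide scan (PheWAS) of one burden across a catalogue,
8. joint modelling of a polygenic score (PRS) and rare-carrier status.

## 2. Variant classification and burden model

A variant's functional class is derived from its annotation:

| class | rule |
|---|---|
| PTV | consequence in {stop_gained, splice_donor, splice_acceptor, frameshift} **and** LoF confidence `HC` |
| missense tier 1 | missense with MPC > 3 |
| missense tier 2 | missense with 3 ≥ MPC > 2 |
| missense tier 3 | other missense (including missing MPC) |
| synonymous | synonymous |
| other | anything else; also low-confidence PTV calls |

Gene constraint stratifies units into pLI ≥ 0.9 (high) vs < 0.9 (low);
missing pLI is "unknown". Rarity is an *in-cohort* minor-allele-frequency
filter, strictly `maf < threshold` (default 1e-5; see §5 on scaling).
Burdens sum dosages over qualifying variants; missing genotypes
contribute 0 (carriers are defined by observed alternate alleles). Units
with fewer than 10 carriers are excluded from gene-level scans.

Common-variant QC keeps call rate ≥ 0.9, Hardy–Weinberg χ² p ≥ 1e-15 and
MAF ≥ 0.01. The MAC→MAF helper converts a minor-allele-count cutoff to a
frequency as MAC / 2N.

## 3. Phenotype preparation

The covariate design contains sex, age, age², sex×age, sex×age², the
leading principal components (20 by default in the generator), and
recruitment-center indicator variables. Quantitative phenotypes are
rank-based inverse-normal transformed (Blom offset 3/8: Φ⁻¹((r − 3/8) /
(n + 1/4)), average ranks for ties), then residualized on the covariates
where the method requires it. Outliers beyond k = 5 SD are excluded in
one pass before transformation in the PheWAS path.

## 4. Two-step whole-genome regression

Step 1 (implemented in `wgr.step1_ridge_loco`) follows the stacked block
ridge design popularized by whole-genome regression tools:

- Genotypes are mean-imputed, centered and scaled by √(2p(1−p)).
- Level 0: variants are split into blocks (default ≤1000 per block,
  within chromosome). For each block and each value of an h² grid
  (default 0.01, 0.1, 0.25, 0.5, 0.75, mapped to ridge penalty
  λ = m(1−h²)/h² for m block variants), out-of-fold predictions are
  produced by k-fold cross-validation (k = 10).
- Level 1: for each left-out chromosome c, a ridge regression stacks all
  level-0 predictions from blocks **not** on c; the penalty is chosen by
  the same k-fold CV, and the fitted combination gives the LOCO
  prediction column c.

The exclusion contract is structural: column c is a function only of
genotypes off chromosome c (verified exactly by permutation tests).
Step 1 expects a covariate-adjusted, standardized phenotype.

Step 2 subtracts the unit's LOCO column from the phenotype and runs OLS
of the offset phenotype on burden + covariates (t-test p, ±1.96 SE CI).
With a zero or absent offset it reduces exactly to the plain linear
burden test.

## 5. Synthetic cohort generator

The generator (`simulate`) produces: common genotypes under
Hardy–Weinberg sampling with MAF ~ U[0.01, 0.5] in contiguous chromosome
blocks (optionally with a latent ancestry gradient); optional sibling
pairs built from shared parental haplotypes (expected genotype
correlation 0.5); ultrarare variants drawn per gene as
Binomial(n, carrier_rate) carriers, one heterozygous singleton per
carrier, class labels from a configurable mix (default ≈7% PTV, 59%
missense, 34% synonymous) and a pLI stratum; covariates; and a
standardized quantitative liability

  trait = covariate effects + polygenic component (variance h², default
  0.3) + Σ_g β_g · burden_g + Gaussian noise scaled so Var(trait) = 1.

Binary traits threshold the same liability at the quantile implied by
the target prevalence. For *known odds ratio* scenarios a liability
threshold cannot carry a prescribed OR, so a logit-linear generator is
provided: logit P(case) = logit(prevalence) + log(OR)·burden.

Scaling caveat: a population MAF threshold of 1e-5 is vacuous at
desk-scale n (a singleton among 10,000 samples already has in-cohort MAF
5e-5). The generator therefore parameterizes rarity by carrier rate
(default 1/1900 per gene, the per-gene PTV carrier-rate anchor of a
large biobank) and records realized in-cohort MAF; analysis scripts pass
an in-cohort-scale threshold to the rare filter.

Determinism: a fixed `SimConfig` (including seed) gives bit-identical
output; the common, rare and phenotype stages use seed, seed+1, seed+2.

## 6. Association tests and inference

- **Linear:** OLS; p from the t distribution at residual df; CI from the
  same t quantile.
- **Logistic:** statsmodels ML logistic; Wald p and ±1.96 SE CI on the
  log-OR; separation/non-convergence reported via a `converged` flag
  (infinite-SE fits are flagged too) so callers can fall back to Firth.
- **Firth:** Newton iterations on the Jeffreys-penalized likelihood with
  the modified score U* = X'(y − μ + h(½ − μ)) (h = weighted hat-matrix
  leverages) and step-halving on the penalized likelihood. Non-intercept
  columns are standardized internally — the Firth estimate is exactly
  equivariant under nonsingular linear maps of the design, because the
  penalty changes only by an additive constant — which makes convergence
  scale-invariant and keeps the information matrix well conditioned; the
  estimate and covariance are mapped back. P-values: Wald (default) or
  penalized likelihood ratio. In a 2×2 table with a zero cell the Firth
  estimate equals the Haldane (+½ per cell) log-OR.
- **Multiplicity:** Bonferroni α/m; Benjamini–Hochberg step-up q-values.
- **Inflation:** λ_GC = median(χ²)/0.4549 (χ² from two-sided p, 1 df).
- **Meta-analysis:** DerSimonian–Laird random effects with fixed-effect
  weights w = 1/se², τ² = max(0, (Q − (k−1)) / (Σw − Σw²/Σw)), combined
  weights 1/(se² + τ²), normal two-sided p. τ² is truncated at zero (the
  textbook estimator); note statsmodels' `combine_effects` reports the
  untruncated moment estimate.

## 7. PheWAS rules

Binary phenotypes need ≥100 cases; they are tested by logistic
regression, and any with Wald p < 0.01 (or a non-converged fit) is
refit with Firth, whose result replaces the plain one. Quantitative
phenotypes need ≥100 observations; >5 SD outliers are removed, then
rank-INT and linear regression. The phenome-wide threshold is α over the
catalogue size (the convention biobank scans print); α over tests
actually run is also reported.

## 8. PRS and joint model

PRS = Σ weight × effect-allele dosage, with missing dosages mean-imputed
per variant; weights are matched to the genotype table by variant ID,
dosages flipped when the effect allele is the reference allele, and
strand-ambiguous (A/T, C/G) or allele-mismatched variants dropped.
Carrier flags mark samples with ≥1 qualifying PTV (or damaging missense,
MPC > 2) allele in constrained genes; the flag builder's pLI rule is
strict (pLI > 0.9) by default with an inclusive (≥) option, matching the
convention of joint PRS/carrier analyses rather than the ≥ 0.9 stratum
definition used for burden stratification. The joint model is OLS of the
phenotype on standardized PRS + PTV flag + missense flag (optionally
with PRS×flag interactions); partial R² for a term is
(SSE_reduced − SSE_full)/SSE_reduced. Quantile summaries report the
phenotype median by PRS quantile × carrier stratum.

## 9. Limitations

- No linkage disequilibrium in the generator: common variants are
  independent given allele frequencies; LOCO behaviour under realistic
  LD is not exercised.
- Single-variant-per-carrier rare model (compound heterozygotes and
  recurrent variants are not generated, though burdens handle them).
- The WGR step-1 is a faithful small-scale re-implementation, not a
  performance-engineered tool: it is dense-matrix in memory and intended
  for ~10⁴–10⁵ samples.
- Firth p-values default to Wald; the penalized-likelihood-ratio option
  is more accurate in tiny samples but slower.
- λ_GC on a few hundred tests is itself noisy (the median of m χ²
  draws); calibration claims rest on the type-I-error suites instead.
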