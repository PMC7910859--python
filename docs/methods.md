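# Methods

## Statistical model

The pipeline analyses the triad (X, M, Y) = (haplotype dosage, log TG,
log HDL-C) with covariates C = (age, sex, BMI, smoking):

* `M = a0 + α X + c'C + ε₁`, ε₁ ~ N(0, σ²_tg)
* `Y = b0 + γ′ X + β M + d'C + ε₂`, ε₂ ~ N(0, σ²_hdl)

Marginalising M gives the total-effect model `Y ~ X + C` with X-coefficient
αβ + γ′; on any complete-case dataset with identical covariates this identity
is exact OLS algebra, and the package asserts it to 1e-10. The indirect
effect αβ is tested with the Sobel z-statistic using the first-order
delta-method SE √(β²SE²α + α²SE²β); the Aroian variant (adding SE²αSE²β) is
available behind a flag and is never smaller. The four criteria are: (1)
α significant, (2) β significant given X, (3) total effect significant, (4)
Sobel test significant, all two-sided at the 0.05 level by default.
*Mediation* requires all four plus |γ′| < |total|; *suppression* requires 1,
2 and 4, opposing signs of αβ and γ′, and |γ′| > |total| — criterion 3 is
deliberately not required, because cancelling paths can leave a null total
effect. The magnitude comparison is on absolute values. Exposure direction
follows the dosage of the named haplotype; flipping the coding (2 − dosage)
flips the sign of α, γ′ and the Sobel z.

"Generalised linear model on log-transformed lipids" is implemented as
Gaussian OLS (statsmodels), which is what unstandardised coefficients with
Wald p-values correspond to. Logarithms are natural by default; the base is a
configuration option and the generator and estimator always share it (β is
base-invariant, α and γ′ are not).

## EM phasing

Haplotype frequencies over a window of k ≤ 16 SNPs are estimated by EM under
Hardy–Weinberg random pairing. The E-step enumerates every ordered diplotype
consistent with an individual's non-missing calls — missing sites are
marginalised, not dropped; listwise deletion applies only at the regression
stage — weighting each by the product of current frequencies; the M-step sets
each frequency to its expected gamete count over 2n (individuals with no
calls at all are excluded from n). Individuals are grouped by genotype
pattern, so cost scales with the number of distinct patterns (≤ 3^k), not n.

Numerical choices: initialisation at the product of marginal allele
frequencies (deterministic; the 3-SNP likelihood is well behaved, so random
restarts are unnecessary and are not the default); convergence when the
largest absolute frequency change is below 1e-8, capped at 1000 iterations;
the log-likelihood trace is recorded and must be non-decreasing. Haplotypes
are reported sorted by descending frequency and labelled H1, H2, …;
zero-frequency haplotypes (< 1e-10) are pruned and the negligible posterior
mass renormalised. Hard diplotype assignment takes the maximum-posterior
unordered pair with lexicographic tie-breaking, but covariate-adjusted
association uses the expected (posterior-weighted) dosage by default for
statistical efficiency; hard counts are available.

Reporting keeps only haplotypes with frequency > 1% (configurable); the
dropped mass is recorded so retained frequencies still describe the full
distribution (with the default generator the three retained haplotypes carry
99.9%).

Pairwise LD runs the same EM on the two-SNP window: D = p_AB − p_A p_B,
D′ = |D|/D_max, r² = D²/(p_A p_a p_B p_b); monomorphic SNPs raise an error
since the statistics are undefined. The HWE test is the 1-df chi-square
goodness-of-fit by default, with the conditional exact test as an option;
monomorphic SNPs return p = 1 by convention.

## Quality control

Per-SNP filters run in a fixed order — missingness > 3%, then MAF < 0.05,
then HWE p < 1e-6 — and the report records each SNP's statistics and the
first failing rule. Sample-level call-rate filtering is the complementary
reading of the same 97% threshold. An empty post-QC matrix is an explicit
error, not an empty table.

## Synthetic cohort generator

The generator emulates the study conditions the analysis assumes: n = 4000
individuals; haplotypes TCG/CTA/CCA/TTA at frequencies
0.613/0.361/0.025/0.001 drawn i.i.d. per gamete (the rare fourth haplotype
closes the distribution and exercises the 1% reporting filter); path
coefficients α = −0.053, β = −0.22, γ′ = −0.033. Covariates: sex male with
probability 1734/4000; age normal(48, 13.3) truncated to [20, 80] (SD ≈
IQR/1.35 for the reported 39–57 interquartile range); BMI normal(24.1, 3.5)
truncated positive; smoking Bernoulli with sex-specific rates 0.329 (men)
and 0.054 (women). Residual SDs default to σ_tg = 0.5 and σ_hdl = 0.3,
realistic log-lipid dispersions; covariate effects are chosen so men have
higher TG and lower HDL-C. Age and BMI enter the linear predictors centred
at their means, and the intercepts (4.486, 5.069) put the median simulated
TG near 94 mg/dL and HDL-C near 53 mg/dL. Total and LDL cholesterol are
drawn from truncated normals with no genetic effect — they are descriptive
columns only. Null SNPs are unlinked HWE sites with MAF uniform on
[0.05, 0.5] on dummy chromosomes; the focal SNPs sit on chromosome 15 at
promoter coordinates. Optional missingness is injected completely at random.

What the generator does **not** emulate: genome-scale LD structure,
population stratification, genotyping-batch artefacts, skewed covariate
distributions, or any dependence of missingness on genotype or phenotype.
Passing recovery tests therefore demonstrate correctness of the estimators
under the assumed model, not robustness to real-data pathologies.

Because the residual lipid variances of the source cohort are unknown, the
recovery tolerances are derived from the simulator's own Monte-Carlo
standard errors (4 SEs of the replicate mean), not from published standard
errors.

## Validation experiments and problem sizes

`haplomed.calibration.recovery_replicates` runs the full pipeline per seed.
The standard experiment uses 100 replicates of n = 4000 (a few seconds of
CPU): EM recovers freq(H1) within multinomial error, the three path
coefficients are recovered without detectable bias, and the mediation run on
the EM dosage classifies suppression in every replicate. Sobel type-I error
under α = 0 is checked over 500 replicates of n = 4000 and is conservative
(≤ nominal). Bootstrap-CI coverage under the null is checked at n = 300 with
120 resamples over 200 replicates — smaller than the flagship cohort because
the experiment multiplies three sampling layers; percentile intervals at
this size still cover ≈ 95%.

## Known limitations

* The EM window is capped at 16 SNPs by exhaustive haplotype enumeration;
  this tool targets small candidate windows, not chromosome-scale phasing.
* Mediation is fitted as a fixed triangular path model on observational
  data; as usual, "direct" and "indirect" are causal only under the model's
  no-unmeasured-confounding assumptions.
* The mediator and outcome are fixed to TG and HDL-C (the intended use);
  generalising the variable names is plumbing, not statistics, and was left
  out to keep the interfaces concrete.
* Sample-size-zero groups, monomorphic exposures and rank-deficient designs
  raise explicit errors rather than returning NaNs.
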