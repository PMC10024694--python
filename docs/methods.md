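# Methods

## The model

`famgreml` decomposes variance in a child phenotype into the contribution
of the child's own common genetic variation (direct genetic effects), a
parent's genetic variation acting through the rearing environment (genetic
nurture / indirect genetic effects), and their covariance (passive
gene-environment correlation: parents transmit both trait-associated
alleles and a correlated environment).

For a dataset of `n` parent-child pairs with covariate-residualized,
standardized child phenotypes `y`, the model is the linear mixed model

    y ~ N(1*mu, V),
    V = V_o * A_c  +  V_p * A_p  +  V_op * (A_cp + A_cp')  +  V_e * I

where

- `A_c` is the genomic relatedness matrix (GRM) among children:
  `A_jk = (1/M) sum_i (x_ij - 2p_i)(x_ik - 2p_i) / (2 p_i (1 - p_i))`,
  the average product of allele-frequency-standardized genotypes over `M`
  QC-passed SNPs, with missing genotypes skipped pairwise;
- `A_p` is the same estimator among the corresponding parents;
- `A_cp` is the rectangular child-by-parent cross matrix (row `i`, column
  `j` = relatedness between child `i` and the parent of family `j`); its
  own-family entries concentrate near 0.5;
- `V_o`, `V_p` (`V_m` maternal or `V_f` paternal), `V_op`, `V_e` are the
  variance components.

One allele-frequency reference — pooled over all children and parents in
the pair dataset — standardizes every matrix, keeping within- and
cross-generation relatedness on one scale.

Because the symmetrized cross structure contributes `2 * 0.5 * V_op` to
each diagonal entry, total phenotypic variance decomposes as
`V_o + V_p + V_op + V_e ~= 1` on the standardized scale, and the combined
genetic variance is defined as the plain sum

    G = V_o + V_p + V_op,

with a delta-method standard error (sum of all entries of the genetic
block of the parameter covariance).  This additive convention is the one
consistent with reporting each component as a proportion of phenotypic
variance.  The offspring-only model (`V = V_o A_c + V_e I`) is standard
SNP heritability; comparing the full model against it with a
likelihood-ratio test (2 extra parameters, chi-square df = 2) tests the
joint null of no nurture and no covariance.

## Estimation

Restricted maximum likelihood with the criterion

    logL = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],   X = 1,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1.

Optimization is average-information (AI) REML: Newton-type updates using
the AI matrix `AI_kl = 1/2 y' P S_k P S_l P y` and gradient
`-1/2 [tr(P S_k) - y' P S_k P y]`.  Numerical safeguards, chosen because
the AI matrix is only an approximation of the curvature and the n <= 50
regime exposes strongly curved likelihood ridges:

- **Levenberg-style damping.**  If the undamped AI step does not improve
  the likelihood, the AI diagonal is inflated (`lambda` starting at 1e-4,
  growing tenfold per rejection, decaying on acceptance), bending the step
  toward the gradient.  An EM step is the fallback of last resort.
- **Constraints.**  `V_o`, `V_p`, `V_e` are floored at zero by projection;
  the covariance `V_op` is unconstrained in sign.  A parameter pinned at
  zero with an outward gradient is frozen out of the update.  `V_e` keeps
  a floor of `1e-8 * var(y)` so V stays invertible.
- **Convergence** is declared when the Newton decrement over the free
  parameters — the predicted log-likelihood gain of the next undamped step
  — falls below `1e-8 * max(1, |logL|)` (default; tests of oracle
  equivalence tighten it to 1e-12).  A plain `|delta logL|` criterion is
  not used because heavily damped steps can make negligible progress far
  from a stationary point.  Hitting 100 iterations flags the fit
  non-converged; the last iterate is still returned.
- **Standard errors** are square roots of the diagonal of the inverse AI
  matrix at the optimum (reported also for boundary estimates, matching
  common GREML software); a singular AI matrix yields absent SEs.

Exact zeros in fitted components are genuine boundary solutions: under a
true null the constrained nurture variance lands exactly on zero in
roughly half of replicates, which is why published component tables show
exact `0.000` entries.  The df-2 chi-square LRT is conservative at this
boundary (the asymptotic null is a chi-square mixture); the plain
chi-square is used because it is the convention of the software family
this pipeline mirrors, and the type-I error consequence (rejection rate
~0.01–0.05 at alpha = 0.05) is verified by simulation in the test suite.

Covariates (child sex, genotyping batch, ten genotype principal
components) are regressed out of the phenotype by OLS before REML, and
residuals are scaled to unit variance, so components are directly
proportions of residual phenotypic variance.  Fitting covariates as fixed
effects inside REML instead would change estimates only at
O(#covariates/n), negligible at the sample sizes involved.

## The simulator

The generator emulates the input the pipeline would receive from a family
cohort: `n` unrelated nuclear families; per-SNP allele frequencies
`p_j ~ Uniform(maf_low, maf_high)` (defaults 0.05–0.5); parental genotypes
Binomial(2, p_j) under Hardy-Weinberg equilibrium with spouses independent
(an assortative-mating knob exists but is off by default); child alleles
by fair Mendelian transmission.  Phenotypes follow

    y = Z_c w_o + Z_m w_m + Z_f w_f + beta_sex*sex + batch offset + e

with `Z` the true-frequency-standardized causal genotypes.  Effect vectors
are constructed with exact norms and inner products (Gram-Schmidt): `|w_o|^2
= v_o`, `|w_m|^2 = v_m`, `w_o . w_m = rho_m * sqrt(v_o v_m)`.  Since parent
and child standardized genotypes correlate 0.5, the implied covariance
component is exactly `v_om = rho_m * sqrt(v_o v_m)` (`expected_components`
returns these closed forms), and the genetic + residual part of the
phenotype has unit population variance.  Causal SNPs are drawn uniformly
without replacement; Gaussian effects per standardized genotype match the
GRM's standardization so the configured fractions are the REML estimands.

Default architecture (`SimulationConfig()`): 3000 families, 2000 SNPs (all
causal), `v_o = 0.30`, `v_m = 0.15`, `rho_m = 0.5` (so `v_om ~= 0.106`),
no paternal nurture, `beta_sex = 0.2`, three batches with offsets
(0, 0.1, -0.1).  These are the canonical recovery conditions used
throughout the tests; effect sizes sit in the range reported for childhood
psychiatric symptom scales.

Questionnaire items are generated by thresholding the latent standardized
score plus unit-variance item noise into ordered categories.  The built-in
scales are the 13-item / 3-category SMFQ (depressive symptoms, at most 2
missing items), the 16-item / 4-category RS-DBD disruptive scale (at most
3 missing), and the 18-item / 4-category RS-DBD ADHD scale (at most 4
missing); item coding starts at 1, so the attainable ranges are 13–39,
16–64 and 18–72.  Category probabilities are skewed toward the lowest
category as in population symptom data; the defaults imply scale means of
roughly 14.9 (SMFQ), 20.3 (disruptive) and 26.5 (ADHD).  Missing items
are masked independently; scoring imputes a missing item with the mean of
the respondent's observed items (totals are left non-integer) and
invalidates respondents beyond the per-scale missingness cap.

What the simulator does **not** emulate: linkage disequilibrium (SNPs are
independent), population stratification or ancestry mixture, sibling sets
or multi-generation pedigrees, X-chromosome transmission, genotyping error
or imputation-quality variation (the INFO stub is a constant 0.99), rater
bias in questionnaire responses, and assortative mating by default.
Passing tests therefore demonstrate the correctness of the estimation
machinery under the model's own assumptions, not robustness of the design
to these real-data complications — in real cohorts, stratification and
assortative mating can masquerade as nurture.

## Scale considerations

- **Relatedness pruning vs panel size.**  The pruning cutoff 0.025 is
  meaningful when GRM off-diagonal sampling noise (sd ~ 1/sqrt(M)) is far
  below it, as with millions of SNPs.  At simulation panel sizes (hundreds
  to thousands of SNPs) the noise sd is 0.01–0.06, and greedy pruning at
  0.025 would remove most of an entirely unrelated sample.  The pipeline
  default remains 0.025; small-panel runs should set a cutoff a few noise
  sd's above zero (tests use 0.2 at M ~= 300–2000).  Pruning is greedy
  most-connected-first at the family level (both members of a removed
  family leave together); a child's relatedness with its own parent is
  exempt.
- **HWE exact test** (two-sided, conditional hypergeometric: the p-value
  sums probabilities of all heterozygote counts no more probable than
  observed) is evaluated in founders (parents) by default, since children
  duplicate parental alleles.
- **Problem sizes in the test suite** were chosen to make Monte-Carlo
  checks sharp at desk scale: single-fit recovery at 3000 pairs x 2000
  SNPs, 30-replicate bias at 1000 pairs, 200-replicate LRT calibration at
  800 pairs x 1000 SNPs, oracle equivalence at 50 pairs x 60 SNPs (small
  panels deliberately increase relatedness variance, which sharpens
  identification), GRM calibration at 500 x 5000.
- **PC computation**: top-k left singular vectors of the
  sample-frequency-standardized genotype matrix, after optional windowed
  LD pruning (window 50 / step 5 / r^2 0.2, on by default in the
  pipeline); signs fixed by making each PC's largest-magnitude entry
  positive.

## Known limitations

- The maternal and paternal models are fitted separately (each conditions
  on one parent); a joint mother-father-child model and
  relatedness-disequilibrium approaches are out of scope.
- The LRT boundary mixture correction is noted but not applied (see
  above); reported p-values for the nurture test are conservative.
- Pre-residualization of covariates (rather than fixed effects inside
  REML) is exact only as n grows; the difference is negligible at the
  sample sizes the pipeline targets but is a genuine approximation at
  n < 100.
- GCTA binary GRM files are written with float32 precision; round-trips
  are exact only to that precision.
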