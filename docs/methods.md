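# Methods

## Problem

Polygenic-score-by-environment (PRS×E) regressions are the standard way to
test genotype-by-environment interaction (G×E) between two complex traits at
biobank scale: per-SNP interaction effects are estimated in a discovery
sample by a genome-wide environment interaction study (GWEIS), aggregated
into polygenic scores, and the score×exposure product is tested in an
independent target sample. Two failure modes make naive versions of this
test unreliable:

1. **Residual heteroscedasticity.** If the outcome's residual variance grows
   with the exposure level ("residual-by-environment interaction"), the
   product term picks up the variance trend and the test rejects without any
   true G×E.
2. **Causal misspecification.** If the exposure/outcome roles are assigned
   backwards, the observed exposure phenotype carries a component of the
   outcome's G×E signal through the phenotypic causal path, and the reverse
   regression rejects spuriously.

The package implements the genetic causality inference model (GCIM): replace
the observed exposure phenotype with the exposure's *polygenic score* inside
the interaction term, and fit the model in both causal directions. The PRS
substitution removes the residual covariance channel — a polygenic score is a
function of genotype only, so it cannot carry the environmental/residual part
of the exposure — which is exactly the part responsible for both artifacts.

## Models

With ĝ_y the outcome's additive PRS, ĝ_y(g×e) its interaction-effect PRS
(both from GWEIS of the outcome), ĝ_c the exposure's additive PRS (from a
plain GWAS of the exposure), and c_t the observed exposure in the target
sample:

| model | design | tested term |
|---|---|---|
| M1 (Plomin-style) | y ~ ĝ_y^gwas + c_t + ĝ_y^gwas⊙c_t | β₃ |
| M2 (Tang-style) | y ~ ĝ_y + c_t + ĝ_y(g×e)⊙c_t | β₃ |
| M3 (GxEprs) | y ~ ĝ_y + c_t + ĝ_y(g×e) + ĝ_y(g×e)⊙c_t | β₄ |
| M4 (GCIM) | y ~ ĝ_y + c_t + ĝ_y(g×e) + ĝ_y(g×e)⊙ĝ_c | β₄ |

M1's additive score comes from a plain GWAS of the outcome (it predates
GWEIS-based scores); M2–M4 use the GWEIS additive score. Both additive
scores are cached in the `PRSBundle`. The reverse direction rebuilds
everything with the trait roles swapped: GWEIS of c with y as the interacting
exposure, GWAS of y, and a Model-4 design c ~ ĝ_c + y_t + ĝ_c(g×e) +
ĝ_c(g×e)⊙ĝ_y. One shared discovery/target split (80/20) serves both
directions so direction asymmetry cannot arise from split noise.

The interaction coefficient is tested by a Wald test (t reference for linear
fits, normal for logistic). Binary outcomes use a logistic link throughout
(GWEIS, GWAS, and target models). The direction call compares the two
interaction p-values against a Bonferroni-adjusted threshold alpha/n_tests:
forward-only significance → "forward", reverse-only → "reverse", both →
"bidirectional", neither → "none". `n_tests` is supplied by the analyst
(e.g. 66 for a 3×11-pair, two-direction screen); the package does not rank
bidirectional results by p-value.

## Synthetic-data generator

The generator emulates the simulation design used to validate the method:

* **Genotypes** — independent biallelic SNPs, counts ~ Binomial(2, f) with
  f ~ U(0.01, 0.5) per SNP. Real genotype panels have linkage
  disequilibrium; we deliberately simulate without LD because the claims
  under test (calibration, power, direction asymmetry) concern the joint
  distribution of phenotypes and aggregate scores, not local correlation
  structure. Passing tests therefore say nothing about LD-induced effects
  (e.g. clumping behaviour) on real data.
* **Causal effects** — a random subset of `n_causal` SNPs receives effect
  triplets (β_add, β_g×e, β_add_c) drawn i.i.d. multivariate normal with
  per-SNP covariance = (summed matrix)/n_causal. The summed matrix puts
  var(β_add)=0.4 (0.3 under the G×E alternative, which moves 0.1 into
  var(β_g×e)), var(β_add_c)=0.5, and a genetic covariance chosen to give
  correlation 0, 0.4, or 0.8 (cov = 0.179/0.358 at variances 0.4/0.5, with
  analogous values at other variance levels; `implied_cov` rounds
  cor·√(v₁v₂) to 3 decimals, matching the conventional values exactly).
* **Residuals** — per-individual triplets (ε_y, ε_r×e, ε_c) are multivariate
  normal with var(ε_y)=0.6, var(ε_c)=0.5, cov(ε_y,ε_c) at correlation 0,
  0.4, or 0.8. Switching heteroscedasticity on moves 0.5 of the outcome's
  residual variance into ε_r×e (var(ε_y)=0.1, var(ε_r×e)=0.5), keeping the
  total at 0.6. ε_r×e is independent of the other two components.
* **Phenotypes** — with G the column-standardized genotype matrix, the
  exposure is generated first, c = G·β_add_c + ε_c, then the outcome
  y = G·β_add + β_c·c + (G⊙c)·β_g×e + ε_r×e⊙c + ε_y. Column
  standardization makes the summed per-SNP variances equal the configured
  components exactly, so each trait has unit total variance under the
  default settings. The residual-by-environment term enters as ε_r×e⊙c
  (each individual's extra residual scaled by their exposure value): the
  design only fixes var(ε_r×e)'s slot in the covariance matrix, and this is
  the canonical generator of residual variance that grows with the
  environment. β_c = 0.447 makes the exposure main effect explain 20% of
  outcome variance (0.447² ≈ 0.2, with var(β_add) reduced to 0.2 to keep
  unit variance).
* **Binary traits** — the quantitative pair is simulated first and then
  transformed: top-decile thresholding makes the ceil(n×prevalence) largest
  values cases (ties broken by index order, measure-zero for continuous
  draws). The generative interaction therefore always acts on the
  *continuous* exposure, and the analysis models see the thresholded 0/1
  variables — a deliberate mismatch that is part of what the binary-trait
  scenarios stress. The latent continuous values are retained on the
  `PhenotypePair` for diagnostics. (The alternative reading — regenerating
  the outcome from the dichotomized exposure — shrinks the realized
  interaction variance by a factor of E[c²]≈prevalence and makes the
  binary/binary power scenarios unrepresentative.)

GWEIS regressions use raw 0/1/2 allele counts (not standardized), so PRS
weights have per-allele units compatible with standard scoring tools.
Discovery fits in the simulation harness are covariate-free; real-data runs
pass covariates through as main-effect columns in every design.

## Numerical choices

* **Batched scans.** GWEIS/GWAS fit one small regression per SNP. The linear
  path solves the per-SNP normal equations batched across SNPs (chunked, 256
  SNPs at a time); p-values are two-sided t with n−p df. The logistic path
  runs damped Newton iterations batched across SNPs, warm-started at the
  covariate-only fit, with each SNP's step capped at 4.0 in max-norm and an
  active set that freezes converged SNPs (step max-norm < 1e-6). Both paths
  are pinned to statsmodels / explicit normal-equations oracles in the test
  suite (coefficients to 1e-8 linear / ~1e-6 logistic).
* **Separation and monomorphism.** Monomorphic SNPs, singular designs, and
  logistic fits that diverge (|β| > 1000) or fail to converge in 40
  iterations are retained as flagged rows with null estimates — indices stay
  aligned with the genotype matrix — and their weights score as zero. At the
  default desk scale roughly 2% of SNPs are flagged in
  binary/binary scenarios, mostly low-MAF SNPs with quasi-separated
  interaction columns.
* **Standardization.** Score vectors are z-standardized before model fitting
  (default). Wald p-values of the interaction are invariant to column
  scaling (tested to 1e-6); standardization only improves conditioning.
* **Degenerate inputs.** Zero-variance covariance components produce exact
  zeros (the singular normal is sampled on its support); constant vectors
  cannot be dichotomized; a constant exposure is refused by GWEIS;
  rank-deficient target designs raise a collinearity error naming the
  aliased columns.

## Scenario harness

`run_scenario` loops replicates (seed = base_seed + replicate index), each
with fresh genotypes, effects, phenotypes, split, scans, bundles and model
fits, and reports empirical rejection rates with binomial Monte-Carlo
standard errors; replicate-level failures are excluded, and more than 10%
failures aborts the scenario. Contrasts between rejection rates are judged
in units of these SEs rather than fixed tolerances since the replicate count
is configurable.

Default problem sizes are n=4000 individuals, m=1000 SNPs, 200 causal, 200
replicates, chosen as the smallest scale at which every qualitative contrast
in the study design (calibration at 0.05, heteroscedasticity-driven
inflation of M1–M3, reverse-direction inflation of M2/M3, binary-trait power
at var(β_g×e)=0.3, M2's false-positive saturation under misspecification) is
resolvable against binomial noise. The per-SNP signal-to-noise ratio at this
scale differs from a biobank-scale study (discovery n per SNP is ~16× lower,
but there are 200× fewer SNPs diluting the score), so absolute power numbers
are not comparable to the full-scale study — only the ordering and
calibration claims are.

`power_curve` sweeps var(β_g×e) holding var_add + var_gxe constant, so trait
variance stays at 1 along the curve; the additive variance at var_gxe=0.3 is
therefore 0.1. `scenario_grid()` materializes the full 108-scenario design
(3 trait-type combinations × null/alternative × heteroscedasticity on/off ×
3 genetic × 3 residual correlation levels).

## Known limitations

* Independent-SNP genotypes: no LD, no clumping/thresholding interplay, no
  population structure or ascertainment.
* The method tests directional *asymmetry* of the interaction signal; it
  does not estimate an identified causal effect, and a "forward" call is
  evidence, not proof, of the forward mechanism.
* GCIM trades power for specificity: replacing the observed exposure with
  its PRS discards the non-genetic part of the exposure, so its power is
  visibly lower than M2/M3 — particularly for binary outcomes — and the
  desk-scale harness reproduces that trade-off.
* Logistic GWEIS at 10% prevalence with rare minor alleles flags a small
  percentage of SNPs as non-converged; their exclusion slightly shrinks the
  effective score but is identical across models within a replicate.
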