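# Methods

## The estimation problem

Children of less-educated parents score higher, on average, for
depressive, anxiety, and ADHD traits.  Three mechanisms can produce this
association: a causal effect of the rearing environment that parental
education shapes ("genetic nurture" when the parental phenotype is
itself genetically influenced), direct transmission of education-linked
variants that also affect the child's traits, and family-level
confounding.  The trio design separates them: each parent's education is
instrumented by their own polygenic index (PGI), the co-parent's PGI is
conditioned on to separate maternal from paternal effects, and the
child's own PGI is conditioned on to block the transmission path.  The
remaining education coefficients estimate nurture-type effects; the
child-PGI coefficient estimates the direct genetic effect.

## Synthetic cohort generator (`simulate`)

The generator draws a variant panel (frequencies uniform on a
configurable range; raw weights zero-mean normal), parental haplotypes,
education, couples, children by Mendelian transmission, and phenotypes:

- **LD**: within blocks of `ld_block_size` loci, a haplotype's allele
  copies the previous locus's allele with probability
  `ld_adjacent_corr`, otherwise is a fresh Bernoulli(freq) draw; blocks
  are independent and separated by >10,000 kb so default clumping treats
  them as separate loci.  This gives tunable r² decay and exact
  haplotypes for transmission at trivial cost; it is not a
  recombination-map model.
- **Education** (years): `mu + gamma * rawPGI + conf_edu * C + noise`,
  with `mu = 15`, residual SD 2.3 (the scale of a Nordic parental
  cohort).  `gamma` (years per raw-score unit) is calibrated at run time
  so the score explains `pgi_r2` of education variance unless set
  explicitly; the default `pgi_r2 = 0.014` reproduces the regime of a
  strong education PGI explaining ~1.4% of years of schooling.
- **Assortative mating**: couples are rank-matched on education with
  additive matching noise; the noise SD is calibrated by bisection on a
  pilot pairing so the realized spousal education correlation hits
  `am_rho` (including the contribution of the shared confounder, which
  is added after pairing so it is genuinely family-level).
- **Child outcome** (latent, SD ≈ 1):
  `beta_m*edu_m + beta_f*edu_f + eta*stdPGI_child + conf_outcome*C +
  Σ_j alpha_j g_child_j + sex effect + noise`, with per-SNP direct
  effects `alpha_j ~ N(pleiotropy_mean, pleiotropy_sd²)` available for
  exclusion-restriction violations.  ADHD inattention/hyperactivity each
  receive half the structural signal; their sum is the total score.
  Optional discretization rounds and clips to the questionnaire ranges
  (depressive 0–26, anxiety 0–10, ADHD total 0–54); it is off for
  estimator-recovery tests because clipping attenuates planted
  coefficients.  The latent-normal + clip construction is an artifact
  choice — the outcome-generating distribution of real questionnaire
  data is unknown.
- **Measured confounders**: parental trait scores are linear in the
  standard-normal family confounder C (loading 0.5) plus noise; smoking
  (3-level) and parity (5-level) are thresholded latent normals with
  realistic category frequencies.
- **Missingness**: MCAR at a flat rate, or MAR-on-education with a
  logistic model in mean parental education (intercept solved so the
  marginal rate matches).  The ADHD subscales and total share one mask;
  genotypes are never made missing.  The default rate used in the
  acceptance pipeline, 54%, mirrors attrition by child age 8 in large
  pregnancy cohorts.
- **Not emulated**: ancestry structure (the 20 PCs per person are pure
  noise, present only so the covariate sets have realistic width),
  genotyping error, item-level questionnaire responses, demography or
  recombination maps.  Passing tests therefore show the estimators'
  algebraic and sampling behaviour, not robustness to population
  stratification or measurement artifacts.

Simulated GWAS summary statistics publish `gamma * true_weight` plus
sampling noise with per-variant SE `pheno_sd / sqrt(2 f (1-f) N)`, so
exposure betas are on the years-of-education scale and two-sample
estimates are per year; `discovery_n = inf` gives the noiseless limit.

## PGI construction (`pgi`)

Harmonization matches summary statistics to the dosage-coded alleles
(sign-flip on swap, strand flip by complement, strand-ambiguous A/T and
C/G variants dropped when EAF ∈ [0.4, 0.6], irreconcilable pairs dropped
with a logged reason).  Clumping is greedy: smallest-p unclaimed variant
below the threshold becomes an index; unclaimed same-chromosome variants
within the (symmetric, boundary-inclusive) window with r² ≥ threshold
are removed.  Ties on p break by (chromosome, position); the p threshold
is strict `<` 5×10⁻⁸; a missing LD entry counts as r² = 0 with a
warning.  These semantics are declared, not inferred from any external
clumping tool.  Scores are weighted dosage sums standardized within
role (mother/father/child), since effects are interpreted per within-role
SD.

## Imputation (`impute`)

MICE with predictive mean matching, type-1 matching: a posterior draw
`beta* ~ N(beta_hat, sigma² (X'X)⁻¹)` predicts missing rows, donors are
the `knn = 10` observed rows closest in predicted value, one donor is
copied uniformly.  Visit order is increasing missingness; defaults are
m = 5 datasets (desk scale; 50 is the large-study convention) and 10
cycles.  Ordinal covariates are imputed by PMM on integer codes rather
than ordered logistic — a documented divergence chosen to preserve the
observed support without a proportional-odds fitter.  ADHD subscales are
imputed and the total formed passively.  Pooling uses Rubin's rules with
Barnard–Rubin degrees of freedom (correct small-m behaviour); the
classic large-sample df is the `df_com = inf` limit.

One property deserves a note: when outcome missingness depends only on
education and the estimand is the outcome-on-education slope,
complete-case OLS is consistent, so multiple imputation cannot
systematically beat it.  The package's MAR superiority check therefore
uses the outcome **mean** as estimand, where the complete-case estimate
is inconsistent under education-driven missingness and MI (with
education in the model) is not.

## One-sample models (`onesample`)

Four specifications: minimally adjusted OLS (child sex, birth year,
batch dummies, PCs for all three members), confounder-adjusted OLS
(adds parental trait scores, smoking, parity as dummies), MR (both
parents' education instrumented by their PGIs, child PGI excluded) and
within-family MR (child PGI added to the covariates).  The MR default
instruments both parents jointly; a per-parent mode (own PGI as the
instrument, co-parent's PGI as a covariate) is available because both
readings of the design exist in practice.  Outcomes are standardized
with the observed-data mean/SD of the analytic sample and the same
moments applied to every imputed dataset, keeping the estimand fixed.
Inference uses normal critical values by default (large-n setting; t
optional).  Collinear dummies are dropped with a warning via a
Gram-matrix sweep.

2SLS is computed by projection; the clustered sandwich uses structural
residuals `y − X beta_hat` and the factor G/(G−1)·(N−1)/(N−k) (the
Stata clustering convention), verified against brute-force dense
assembly to 1e-10 in tests.  First-stage diagnostics report the
classical R²-based excluded-instrument F, a Sanderson–Windmeijer-style
conditional F (the co-parent's education partialled out via its own
instrument's fitted value), and the partial R² increment of the own
instrument over the covariate-only model.  Which variant a given
published F corresponds to is often unstated, so both are reported.

## Two-sample MR (`twosample`)

Per-variant outcome associations come from one linear model per variant
— outcome on mother, father, and child dosage jointly plus the
within-family covariates — with cluster-robust SEs.  Conditioning on
child genotype is what makes the parental coefficients "within-family".
The covariate block is partialled out once (Frisch–Waugh); the dosage
coefficients, residuals, and their sandwich block are exact under this
shortcut (block-inverse identity, tested against the full solve).
Outcome vectors may come from imputed data (first completed dataset);
SNP data are never imputed.

Estimators: IVW (through-origin weighted LS, weights 1/se_out²;
multiplicative random-effects SE scaled by max(1, sqrt(Q/(J−1)))),
MR-Egger (intercept = directional pleiotropy; exposure betas oriented
non-negative first, the standard identifiability convention), weighted
median (cumulative-weight interpolation at 0.5; delta-method ratio
weights se_out²/bx²), and a mode estimator (weighted Gaussian KDE over
Wald ratios, Silverman bandwidth × phi on a 512-point grid spanning
mean ± 5 SD).  Median and mode SEs use a parametric bootstrap of
(bx, by); fixed seeds make them reproducible.

## Problem sizes and numerical choices

Desk-scale defaults: 20,000 trios, 200 variants, m = 5 imputations —
chosen so the full pipeline runs in seconds while the cluster counts,
instrument strength and missingness fractions stay in the regime of the
real design (40,879 trios, 1729 variants, m = 50, reachable by config).
The simulation-study driver omits the noise PCs (`n_pcs = 0`) since they
contain no signal and only slow the fits.  The coverage study uses 500
replicates of 5,000 trios × 100 SNPs; the bias-law check uses one
replicate of 100,000 trios with a deliberately large direct effect
(η = −0.3 SD) so the closed-form bias dwarfs single-replicate sampling
noise.  Degenerate inputs are rejected loudly: inverted frequency
ranges, constant outcome columns, fully missing variables, fewer
instruments than endogenous regressors, single clusters.

## Known limitations

- The generator's PCs carry no ancestry signal, so confounding by
  population structure — one of the design's real-world threats — is not
  simulated.
- Rank-matched assortative mating is phenotypic and one-generation; no
  equilibrium genetic correlation between spouses is induced beyond what
  matching on education produces.
- PMM imputation of ordinal covariates differs from ordered-logistic
  imputation; with strong ordinal-covariate missingness the pooled
  estimates may differ slightly from that convention.
- Two-sample estimates inherit the GWAS reporting scale of the exposure
  betas; users supplying external summary statistics should check that
  scale before interpreting the slope as "per year".
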