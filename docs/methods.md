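# Methods

## Model and estimation

`famvc` fits Gaussian variance-component models to family-clustered
phenotype data. The observed phenotype is modeled as a mean plus fixed
covariate effects plus a sum of zero-mean random effects: additive
genetic (A), common environment shared by a family (C), environment
shared only by a pregnancy (T), a stable subject effect across repeat
visits (S), and independent unique environment/error (E). Estimation is
two-stage:

1. **Pre-residualization.** The phenotype is regressed by OLS on an
   intercept and the chosen covariates (complete cases per phenotype;
   categorical covariates are expanded against the lexicographically
   first level; exactly collinear columns are dropped greedily in column
   order, which leaves the residuals unchanged). Because the second
   stage fits no fixed effects, its ML estimator coincides with what a
   REML fit of the same random effects would give.
2. **Variance fractions by ML.** The total residual variance is
   estimated unbiasedly as SSR/(n − p), with p the regressor degrees of
   freedom consumed in stage 1 (an `n − 1` variant is available), and is
   then held fixed. The per-family residual covariance is
   σ²·Σ_e f_e M_e with all component matrices having unit diagonal, so
   the fractions f_e live on the simplex and partition the residual
   variance; the A fraction is the heritability estimate. The
   log-likelihood is the sum over families of small multivariate-normal
   log-densities; families are stacked by block size and evaluated with
   batched Cholesky factorizations. A family whose block stays
   non-positive-definite after escalating diagonal jitter
   (10⁻¹⁰σ²…10⁻⁶σ², ×10 steps) contributes −∞, which the optimizer
   treats as infeasible.

Relatedness enters either as pedigree kinship built from family,
birth-date and zygosity labels (MZ pairs 1, every other within-family
pair 0.5 under the all-full-siblings convention, with a per-pair
override table for known half/adopted siblings) or as a SNP-derived
matrix supplied in square-CSV or GCTA-style text form. Either way the
matrix is sparsified to family blocks — relatedness between members of
different families is set to zero — which is what makes the likelihood
block-diagonal and the method scale. SNP matrices are used as supplied:
the diagonal is not forced to 1 and small negative entries are retained;
nearest-PSD repair (eigenvalue clipping at zero) is opt-in and applied
only to blocks that would otherwise be non-positive-definite.

Singleton families deserve a note: their covariance is σ² regardless of
the fractions (the component matrices all have unit diagonal), so they
inform the total variance but are exactly neutral to the component
split. The implementation computes their contribution in closed form so
this neutrality holds to machine precision.

## Optimization

The m−1 free fractions are optimized through a log-ratio transform with
E as reference (coordinates clipped at ±30; saturation is treated as a
boundary). Nelder-Mead runs from a fixed deterministic set of starts —
equal fractions, plus each effect at 0.9 — with tolerance 10⁻⁹ on the
log-likelihood and at most 5000 evaluations per start; the best
likelihood wins, ties going to the earliest start, and the winner is
restarted once. Because the likelihood surface is numerically flat below
~10⁻¹³ nats, any comparison-based search leaves ~10⁻⁷-level
indeterminacy in the optimum; interior optima are therefore polished by
a finite-difference Newton step (central differences, h = 10⁻⁴), which
pins the stationary point tightly enough that equivalent datasets
(rescaled, permuted, or padded with singletons) produce matching
fractions. Fractions below 10⁻⁸ after optimization are projected to
exactly 0 (the projection is kept only if it does not lose likelihood
beyond 10⁻⁷ nats) and flagged as boundary solutions. Family and
within-family row order are canonicalized inside the likelihood builder,
making the whole fit exactly invariant under observation shuffles.

With `jointly_estimate_total=True` the total variance is instead
profiled by ML for each candidate fraction vector (closed form) and k
increases by one; this is a sensitivity mode, not the default.

## Confidence intervals and model comparison

Profile-likelihood intervals: for a target fraction, the remaining
fractions are re-maximized on their rescaled simplex, and the interval
endpoints are where this profile drops `qchisq(level, 1)/2` nats below
the maximum (1.9207 at 95%). A symmetric three-point quadratic (step
0.02 on the fraction scale, shifted one-sided at the simplex edge)
provides the curvature and the initial crossing estimate; each crossing
is then refined against the true re-maximized profile by bracketed
root-finding, so the endpoint satisfies the threshold condition to well
under 0.05 nats even on skewed profiles. Endpoints are truncated to
[0, 1]. If the fitted curvature is not meaningfully negative the profile
is flat — the classic case is MZ-only data, where the A and C component
matrices coincide and only their sum is identified — and the interval is
reported as (0, 1) with a non-identifiability warning rather than an
arbitrary split.

Model comparison uses AIC = −2 ln L + 2k with k = m − 1 free simplex
fractions (the total variance is estimated outside the likelihood and
not counted; the convention is recorded in every report). ΔAIC between
two fits is computed only when both used the identical observation set,
enforced by row count and a checksum of the rounded residual vector;
otherwise only the per-effect estimate differences are reported. A
useful structural consequence, exercised in the tests: adding a
component whose true variance is zero leaves the likelihood unchanged
whenever its estimate lands on the zero boundary, so the AIC difference
is exactly the penalty 2.0 — and can only be smaller when the added
component absorbs chance variance.

## Synthetic data

The simulator emulates the structure of a large two-visit developmental
cohort with an embedded twin registry: MZ-pair, DZ-pair, full-sibling-
pair and singleton families; one or two visits 24 months apart; baseline
age uniform on [107, 132] months (twins share age and birth date; twin
pairs are sex-concordant, as in same-sex registry recruitment); fixed
effects of age, sex and a practice dummy on the second assessment. Given
true fractions on the simplex, A is drawn per family from the kinship
block (jointly Gaussian), C per family, T per pregnancy, S per subject,
E per observation, each scaled by √(σ²·f). Kinship can be jittered into
a SNP-like matrix: zero-mean Gaussian noise on within-family values, MZ
entries resampled to stay above the 0.9 detection threshold, diagonal
jittered at half the off-diagonal sd; the default noise sd 0.035 is a
plausible stand-in for array-based relatedness error, not an empirical
calibration. Everything is reproducible bit-for-bit from the config
seed, and the truth manifest records the generative fractions and the
realized twin correlations.

What the simulator deliberately does not reproduce: genotype-level
noise structure (relatedness error is i.i.d. Gaussian), assortative
mating, non-additive genetic effects, gene–environment correlation or
interaction, non-Gaussian phenotypes, dropout between visits, and
family sizes beyond two sampled children. Passing recovery tests
therefore demonstrate correctness of the estimator under the stated
generative model, not robustness to those real-data violations.

## Default parameters that matter

| parameter | default | units | why |
| --- | --- | --- | --- |
| total_variance (sim) | 1.0 | phenotype units² | scale-free; engine is scale-equivariant |
| grm_noise_sd | 0.035 | relatedness | plausible SNP-relatedness error; tunable |
| age_slope / sex_effect / practice_effect in validation runs | 0.05 /month, 0.3, 0.2 | phenotype units | realistic covariate signal so residualization is exercised |
| CI level | 0.95 | — | field convention |
| CI stencil step | 0.02 | fraction | large enough that LL differences dominate noise |
| Newton polish step | 10⁻⁴ | log-ratio scale | balances truncation bias vs evaluation noise |
| boundary projection threshold | 10⁻⁸ | fraction | below estimable resolution |

## Validation scale

The test suite validates at sizes chosen to make sampling error small
relative to the asserted tolerances while keeping the default run fast:
likelihood oracle on 20 random instances of ≤ 50 observations against a
dense multivariate-normal density (10⁻¹⁰ agreement); an exhaustive
0.01-step simplex grid search on a 50-family toy; 20 replicates of 1000
families for ACE recovery and Falconer consistency (the Falconer
comparison is between replicate means, since the ML estimator uses
sibling pairs and Falconer's 2(r_MZ − r_DZ) does not, making them
disagree replicate-wise while estimating the same quantity); 10
replicates of 800 two-visit families for ACSE recovery; 10 replicates
for the null-T AIC penalty; and 200 replicates of 500 families for 95%
CI coverage of the heritability fraction.

## Known limitations

- Only univariate phenotypes; no bivariate/multivariate decompositions,
  no random-effect × covariate interactions, no sibling-interaction
  models.
- The T and C components are poorly separated when nearly all
  multi-member families are twin pairs; the flat-direction detector
  reports this rather than resolving it.
- GRMs are consumed, never computed: no genotype handling, pruning or
  ancestry PCs.
- The kinship builder's 0.5-for-all-siblings convention mislabels half
  and adopted siblings unless per-pair overrides are supplied.
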