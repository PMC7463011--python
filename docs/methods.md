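# Methods

## The measurement model

Nine questionnaire subscale scores y are modelled as continuous indicators of
three orthogonal latent dimensions,

    y = ν + Λη + ε,    η ~ N(α, Φ),    ε ~ N(0, Θ),

with a bifactor pattern: every indicator may load on the general
impulsive–compulsive factor, the four UPPS-P subscales may load on an
Impulsivity group factor, and the three OBQ-44 subscales on an Obsessiveness
group factor; factor covariances are fixed to zero. Three paths are fixed at
zero in the default pattern (lack of perseverance on the general factor,
sensation seeking on Impulsivity, and the two IUS-12 subscales on any group
factor), so the general factor carries the IUS-12 entirely. Scaling uses the
reference-variable method — one unstandardised loading per factor fixed to 1
(predictability for the general factor, lack of perseverance for
Impulsivity, perfectionism for Obsessiveness; each reference loads only the
factor it scales, which keeps the scaling stable). Five error covariances
are free by default: urgency–sensation seeking, premeditation–sensation
seeking, predictability–paralysis, perfectionism–predictability,
thoughts–paralysis. They are chosen to be conceptually adjacent pairs
(within-questionnaire, or both reflecting intolerance of uncertainty) while
keeping the model identified: a free error covariance *inside* a
three-indicator group-factor block would leave that group factor's loadings
under-identified, so none is placed there.

Estimation is full-information maximum likelihood. Rows are grouped by
missingness pattern; each pattern contributes through its count, mean and
scatter, so one likelihood evaluation costs the same at 500 rows as at
500,000. Gradients with respect to Λ, ν, Θ, Φ, α are analytic; residual and
factor variances are log-transformed during optimization so the solution
cannot leave the admissible region (a near-zero variance, the Heywood
pattern, shows up as a boundary estimate and is flagged rather than
truncated). The optimizer is L-BFGS-B followed by a damped Newton polish
until the gradient max-norm of −2LL falls below 1e-6, with up to 50 jittered
restarts. Start values: free loadings 0.5, residual variances at half the
observed variances, factor variances at half the reference indicator's
variance, intercepts at the observed means.

Fit statistics follow the FIML conventions: χ² = 2(LL_saturated − LL_model),
where the saturated model is the unstructured multivariate normal fit by EM
under missingness; p from the central χ² survival function;
RMSEA = sqrt(max(χ²−df,0)/(df·n)) with n the number of rows used and a 90%
CI from inverting the noncentral χ² distribution; CFI against the
independence baseline (free means and variances, zero covariances, fit by
FIML to the same rows); SRMR on the covariance metric only, with the
EM-estimated saturated covariance standing in for the sample covariance.
When χ² ≤ df, RMSEA is exactly 0 and CFI exactly 1 by the clamps. A
just-identified model has df = 0 and its RMSEA/CFI are reported as
undefined.

The Bollen–Stine bootstrap transforms complete-case rows so the fitted model
holds exactly, resamples with replacement, refits, and returns the
proportion of bootstrap χ² at or above the observed value; refit failures
are counted and a warning status is raised above 10%. Modification indices
are univariate score tests: the augmented model's analytic gradient and a
finite-difference Hessian at the restricted optimum give the expected χ²(1)
improvement; ties break by indicator order. Post hoc error-covariance
freeing adds the largest-index candidate one at a time and requires the
final added set to jointly survive Benjamini–Hochberg FDR at q = 0.05 on
parameter z tests.

## Invariance testing

The two co-twin subsamples are compared with the cumulative ladder
configural → weak (equal loadings, Δdf 11) → strong (equal intercepts,
Δdf 9) → strict (equal residual variances, Δdf 9) → equal factor variances
(Δdf 3). Error covariances always stay group-specific. Each step is retained
when the Δχ² p exceeds 0.05 (the conventional cut-off; the threshold is a
parameter). If the strict step fails, residual variances are released one at
a time — largest score-test index first — until the step is retained
(partial strict invariance). Latent means are tested after strong
invariance in a separate model with the second group's latent means free
(first group fixed at 0); two-tailed z from estimate/SE. With two groups
each level is warm-started from the previous level's solution, which makes
the ladder nearly an order of magnitude faster without changing the optima.

The two groups are co-twins and therefore not independent samples; the
multi-group likelihood ignores that dependence, as is standard practice in
this design. The type-I calibration test in the suite therefore switches
co-twin resemblance off (all-E generating shares) so that the nominal χ²
reference distribution actually applies.

## Factor scores and measurement error

Regression-method scores are the conditional expectations
η̂ = α + ΦΛ'Σ⁻¹(y − μ), computed with pattern-specific submatrices for rows
with missing indicators; rows with nothing observed get missing scores.
Determinacy per factor is ρ = sqrt([ΦΛ'Σ⁻¹ΛΦ]_ff / Φ_ff), the model-implied
correlation between the estimated and true factor. Scores enter the twin
models as single indicators with error variance fixed per twin subsample.

Two conventions are provided for that fixed error variance. The default,
θ_δ = (1−ρ)·σ², is the convention printed in the applied literature this
pipeline mirrors. The alternative, θ_δ = (1−ρ²)·σ², is the exact
measurement-error variance of regression scores: since Var(η̂) = ρ²Φ and
E[η̂|η] = ρ²η, the part of the score variance not explained by the true
factor is ρ²(1−ρ²)Φ = (1−ρ²)·σ². With the (1−ρ) convention the estimated
variance components are attenuated by roughly a factor ρ; with (1−ρ²) the
recovery chain is unbiased, which is why the acceptance recovery checks use
it. Every report states which convention was applied.

Outliers are screened univariately per factor × subsample at |z| > 3.29
(≈ two-tailed 0.001) and recoded missing; the threshold is a parameter and
constant score vectors yield no flags.

## Twin variance-components models

For each phenotype the paired scores (y₁, y₂) follow a two-group bivariate
normal with the biometric covariance structure: diagonal a²+c²+d²+e² (+ θ_δ
per twin), off-diagonal a²+c²+d² for MZ and 0.5a²+c²+0.25d² for DZ pairs.
E is always present; C and D are mutually exclusive (with MZ/DZ data alone
they are not jointly identified). Path coefficients are the free parameters,
so all variance components are non-negative by construction; a component
estimated at (numerical) zero is flagged as a boundary solution. Means are
per-twin intercepts plus, optionally, a shared age slope with age centered
at the pair-sample mean; by default age enters only the general dimension,
for which the generator builds in a weak negative age effect
(−0.02 latent SD per year, i.e. r ≈ −0.2 over an age SD of ~10, matching
the weak negative association the design anticipates). Pairs with one
missing member contribute through the univariate marginal.

The χ² for each model is taken against a saturated reference fit to the
same cells: per-zygosity free means and unstructured 2×2 covariance (10
parameters; with the age covariate, per-zygosity per-twin slopes are added,
14 parameters). BIC = −2LL + k·ln(n) with n the number of individuals with
any phenotype data by default (a pairs-based n is available behind a flag;
the choice is recorded in the output). Models are compared by equal-prior
BIC weights Pr(Hᵢ|D) = exp(−ΔBICᵢ/2)/Σ exp(−ΔBICₖ/2), computed with
min-subtraction for numerical stability; the preferred model is the highest
posterior, and any model within 0.05 of it is reported alongside. Nested
pairs also get the likelihood-ratio Δχ² test; note that when a variance
component sits on the boundary under the null the Δχ² reference is a
mixture distribution and the nominal-α test is conservative (the suite
checks rejection ≤ α rather than ≈ α for that case).

## The synthetic-data generator

The generator emulates the study conditions end to end: 118 MZ and 55 DZ
complete pairs plus 141 singletons (487 individuals) by default; ages drawn
once per pair from a truncated normal (mean 40, SD 10.5, bounds 18–55);
MZ co-twins share sex, DZ co-twins draw independently. Each latent
phenotype is a·A + c·C + e·E with A shared in MZ pairs and correlated 0.5
in DZ pairs (bivariate-normal draw — the standard additive-genetic
assumption), C shared in all pairs, E independent, and unit total latent
variance. Default variance shares are the published study's point estimates:
general (0, 0.36, 0.64), impulsivity (0.33, 0, 0.67), obsessiveness
(0.25, 0, 0.75) — AE rather than CE for obsessiveness because the additive
hypothesis was the design's prior. The general phenotype additionally
receives the age effect. Indicators are generated from the bifactor model
on a standardized scale (intercepts 0, indicator variances near 1; the
study's raw subscale metrics are not reproduced, so the scale is
arbitrary-but-documented). Default loadings and residual variances are
calibrated so that the population factor-score determinacies equal the
study's printed values (ρ = 0.914, 0.861, 0.814) — the generator should be
as informative an instrument as the study it emulates, no more, no less.
Missingness is completely at random at 5% per cell by default (the study's
per-questionnaire response gaps ranged higher, but its pipeline rows were
largely complete); outliers displace a latent phenotype by ±5 latent SD in
0.2% of individual×phenotype cells, roughly the two-in-a-few-hundred rate
the screening stage is meant to catch.

Randomness flows from a single integer seed through named `SeedSequence`
sub-streams (one per random component: A, C, E, residuals, age, sex,
missingness, outliers, assignment), so datasets are reproducible
bit-for-bit and adding, say, outliers does not reshuffle the phenotype
draws. The closed-form 18×18 co-twin covariance (`population_covariance`)
includes the shared-age pathway and serves as the oracle for estimator
tests.

What the generator does *not* emulate: item-level Likert responses (scores
are continuous), non-random missingness, zygosity misclassification,
sex effects on the phenotypes, and age-moderated genetic effects. Passing
tests therefore demonstrate correctness of the estimators under the model's
own assumptions, not robustness to these real-data violations.

## Problem sizes in the suite

Monte-Carlo checks are sized so the whole suite runs in well under half an
hour on one CPU: cross-twin-correlation and conservation oracles at 50,000
pairs, the population-covariance oracle at 200,000 MZ pairs,
Falconer-vs-ML agreement at 100,000 pairs, invariance type-I calibration
over 200 replicates at 5,000 individuals per group (complete-data fits cost
O(1) in n through sufficient statistics), model-selection consistency over
50 replicates at five times the study's pair counts, Bollen–Stine
calibration over 200 outer replicates of 100 draws on a compact one-factor
model, and variance-component recovery at ten times the study's pair
counts.

## Known limitations

The measurement model treats all individuals as independent rows, including
co-twins, when fit to the combined sample; within-pair dependence inflates
the precision (not the location) of measurement-model estimates. Bollen–
Stine resampling uses complete cases only. The Table-style df conventions of
other software can differ (notably where a published table's internal
−2LL/χ²/df relations are not mutually consistent); this package always
derives df from its own saturated reference and says so in its output.
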