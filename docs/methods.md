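# Methods

This note records the statistical model the package implements, the
defaults and why they were chosen, the numerical choices that matter for
reproducing results, and what the synthetic-data tests do and do not
demonstrate.

## Data model and pre-modelling filters

IPD are one row per patient: study label, treatment label, binary outcome
and baseline covariates. Categorical covariates are expanded into
indicators deterministically (levels sorted alphabetically, first level
as baseline), so the same file always yields the same design.

Three filters run before modelling, in this order:

1. covariates missing in **strictly more than** 50% of records are
   dropped (threshold configurable);
2. of each covariate pair with |Pearson r| **strictly above** 0.7, the
   lower-priority member is dropped. Priority is a user-supplied ordering
   (default: column order) standing in for the subject-matter judgement
   used with real data; correlations use pairwise-complete observations
   and pruning happens after indicator expansion;
3. complete-case restriction on the remaining covariates and the outcome.
   Missingness is assumed ignorable — reasonable when all covariates are
   measured at baseline and the outcome window is fixed — and no
   imputation is attempted.

The pipeline is idempotent: re-applying it to its own output changes
nothing.

## Sample-size adequacy

Events per variable is `events / model_df` where `model_df` counts all
candidate parameters (indicator and nonlinear terms included), reported
to one decimal.

The minimum development size for a binary-outcome model is the maximum of
three criteria:

1. *shrinkage*: `n1 = P / ((S−1) · ln(1 − R²_cs/S))` with shrinkage
   target S = 0.9;
2. *small optimism in apparent fit*: the same formula at
   `S2 = R²_cs / (R²_cs + 0.05 · R²_max)`, bounding apparent-minus-
   adjusted Nagelkerke R² by 0.05;
3. *precise mean risk*: `n3 = (1.96/0.05)² · φ(1−φ)`.

Each criterion is rounded up to a whole patient and the maximum is
reported, together with the implied event count `⌈n·φ⌉`. The anticipated
R² may be supplied on the Cox-Snell scale directly or as a Nagelkerke
value, converted through the prevalence-dependent maximum
`R²_max = 1 − exp(2(φ ln φ + (1−φ) ln(1−φ)))`. This conversion matters:
an anticipated Nagelkerke R² of 0.15 at prevalence 742/2000 corresponds
to Cox-Snell 0.1099 (often quoted rounded as 0.11), and using the rounded
value shifts the criterion-1 size for a 45-parameter model from 3456 to
3452. The package reproduces 3456 and 1076 for 45 and 14 parameters from
the Nagelkerke input; no further "whole-event" re-rounding of the final
n is applied, because the per-criterion ceilings already reproduce both
reference values exactly.

## Stage 1: baseline-risk model

Both routes fit a common-coefficient logistic model on all arms pooled,
blinded to treatment — using only control arms would shrink the effective
sample and can fabricate spurious risk-by-treatment interactions.
Per-study (independent or exchangeable) coefficient pooling is a
recognised variant; the API reserves a field for it but only the common
model is implemented.

**LASSO route.** Covariates are standardized (mean 0, SD 1); the
intercept is unpenalized. The penalty grid is 100 log-spaced values from
the analytic `λ_max = max_k |Σ_i x_ik (y_i − ȳ)| / n` (smallest penalty
with an all-null slope vector) down to `0.001 λ_max`, the usual path
convention. Ten-fold cross-validation stratified by outcome (fold
assignment derived from the seed, so fits are reproducible) scores each
penalty by mean AUC with its standard error over folds; the chosen
penalty is the **largest** one whose mean AUC is within one SE of the
best — the parsimonious reading of the one-SE rule when AUC is maximized.
Coefficients are refit on the full data at the chosen penalty and
reported on the original covariate scale. The underlying solver is
liblinear with a large `intercept_scaling` so the intercept is effectively
unpenalized; at a zero penalty the fit agrees with unpenalized maximum
likelihood to 1e-4.

**Prespecified route.** A fixed variable list is estimated by ridge-type
penalized maximum likelihood: maximize `ℓ(β) − (λ/2) Σ_k β_k²` on the
standardized scale, intercept free, by Newton iterations. Along a penalty
trace (default 0, 0.5, 1, 2, …, 128) the reported penalty maximizes a
modified AIC, `LR χ²(λ) − 2·edf(λ)`, where the likelihood-ratio χ² uses
the unpenalized log-likelihood evaluated at the penalized estimate and
the effective degrees of freedom are `trace(I (I + P)^{-1})` with `I` the
observed information at the estimate and `P` the penalty matrix (the
intercept contributes ≈1). This explicit edf definition is this package's
choice; standard errors come from the sandwich
`(I+P)^{-1} I (I+P)^{-1}`, back-transformed to the original scale. Near
separation at λ = 0 the Newton step is damped and a warning is emitted.

`score()` applies a fit to a table, returning per-patient logit risks and
per-study means; stage 2 centers on the per-study mean of the fitted
scores of that study's analyzed patients.

## Internal validation

The c-statistic is the tie-aware concordance probability (average ranks,
ties count ½); the calibration slope is the slope of a logistic refit of
outcomes on predicted logits, with perfect separation detected directly
and reported as +∞ with a warning. Bootstrap optimism reruns the **whole**
fitting procedure — including any selection — in each of B resamples
(default 500), evaluates each bootstrap model on its own resample and on
the original sample, and subtracts the mean difference from the apparent
performance. Resampling is at patient level, ignoring study structure
(no cluster bootstrap); resamples with a single outcome class are redrawn
up to ten times so exactly B contribute. This is a known simplification
for clustered IPD and is documented as a limitation.

## Stage 2: Bayesian network meta-regression

The mean structure, consistency constraints and parameter roles are as in
the README. Choices that need stating:

- **Baseline arm per study**: the overall reference treatment when the
  study includes it, otherwise the alphabetically first arm.
- **Priors**: Normal(0, variance 1000) on `u_j`, `δ_t`, `γ_0`, `γ_t`.
  The variance reading of "N(0, 1000)" is deliberate (SD ≈ 31.6) and
  configurable, since sampler notations differ on variance versus
  precision.
- **Random-effects extension**: study-level deviations around the common
  contrasts with `σ_D, σ_G ~ Uniform(0, 5)`. With very few studies the
  between-study SD is weakly identified; the common-effect model is the
  default and the one exercised by the acceptance simulations.
- **Sampler**: adaptive random-walk Metropolis. The chain starts at the
  posterior mode (Newton iterations on the penalized likelihood, study
  intercepts initialized at observed baseline-arm log-odds with a ½
  continuity correction, contrasts at zero) and proposes from a
  multivariate normal with the Laplace-approximation covariance scaled by
  `2.38/√d`; the global scale adapts toward 30% acceptance during burn-in
  only, so the retained chain is a valid time-homogeneous Metropolis
  chain. Chains are seeded independently and jittered at initialization.
  Defaults follow the two-chain, 10 000-iteration, 1000 burn-in, thin-10
  convention; R-hat and effective sample size are computed with arviz and
  any R-hat above 1.05 triggers a warning. The contract is distributional
  — the sampler is validated against closed-form log-odds-ratio oracles,
  prior-domination limits and coverage simulations, not against a
  specific MCMC implementation.
- **Network checks**: every treatment must be reachable from the
  reference through the study graph; single-arm studies cannot inform
  contrasts and are rejected here (they may still serve as an anchoring
  population).

Consistency (`D_ht = δ_t − δ_h`, likewise for interactions) holds exactly
per draw because contrasts are derived quantities, never sampled
separately. Because the risk covariate is centered within study, adding a
constant to every score in a study leaves the likelihood's contrast and
interaction terms unchanged; posteriors of `δ`, `γ_0`, `γ_t` are
invariant to such shifts up to Monte Carlo error.

## Anchored predictions and benefit summaries

`α` and the population mean logit risk come from a reference population —
by default the pooled reference arms — via a logistic regression of
outcomes on the centered score (`α` is its intercept; with constant
scores it degenerates to the log-odds of the observed event rate). `α`
is treated as a fixed plug-in by default, matching the two-stage
separation; this understates total uncertainty, a recognised cost of
two-stage estimation, and the anchor can be re-estimated on bootstrap
resamples when uncertainty in it matters.

Group summaries average patient-level probabilities within stratum per
posterior draw (a marginal group risk, not the risk at the stratum's mean
score — with a nonlinear link these differ; the switch is the shape of
the patient set passed in). Stratum cutpoints default to baseline risk
< 30% (low) and > 50% (high) and are purely illustrative conventions.
Pairwise odds ratios divide group-level odds per draw; for a single
patient the identity `OR_t(c) = exp(δ_t + γ_t c)` holds exactly per draw.
NNT is `⌈1/(risk difference)⌉`, defined only for positive differences —
the ceiling convention reproduces both reference NNTs (7 from a
15-percentage-point difference, 10 from 11 points).

## Synthetic data

The generator draws correlated covariates from a latent multivariate
normal (binary covariates by thresholding, so configured correlations act
on the latent scale), computes the true logit risk linearly, assigns
treatments uniformly within each study's arm list, and draws outcomes
from the stage-2 mean structure using the **analytic** study mean of the
logit risk as the centering constant — well-defined at generation time
because the risk is linear in the covariates.

The packaged three-trial configuration mirrors the shape of a real RRMS
network: trial sizes 939/1417/1234 with arm lists
{placebo, natalizumab}, {placebo, dimethyl fumarate, glatiramer acetate},
{placebo, dimethyl fumarate}; placebo-arm intercepts at the logit of the
observed placebo relapse proportions (0.564, 0.410, 0.446); stage-2 truth
δ_DF = −0.89, δ_GA = −0.71, δ_N = −1.22, γ0 = 1.26, γ_DF = 0.25,
γ_GA = 0.23, γ_N = −0.26; and eight mixed covariates whose coefficients
give the true logit-risk score a spread of ≈0.7 around a mean risk near
37%. These values were fixed once, as the study conditions the package
is built to emulate.

What the synthetic data does **not** emulate: real covariate
distributions (skewness, floor effects, ordinal scales), informative
missingness, per-study covariate shift, residual between-study
heterogeneity beyond the risk score, and longitudinal relapse processes.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated generative model, not clinical validity of any
fitted scores.

## Problem sizes used in the test suite

Simulation-backed tests run at sizes chosen to make the checked property
overwhelmingly likely while keeping the default suite fast: calibration
slope limits at n = 30 000; no-selection bootstrap optimism at n = 20 000
with 20 resamples; selection-optimism checks at n = 300 with 20 noise
covariates and 8 resamples over 5 seeds; closed-form log-OR oracles at
n = 10 000; and 20-replicate coverage of the stage-2 parameters at the
full three-trial size (~3590 patients) with 2 chains × 4000 iterations,
thin 10. These are the package's own choices of simulation size.

## Known limitations

- Patient-level (not cluster) bootstrap for optimism correction.
- Common stage-1 coefficients across studies; no per-study or
  hierarchical stage-1 variants.
- One effect-modifying covariate (the risk score); additional modifiers
  or study-level covariates are out of scope.
- Two-stage estimation does not propagate stage-1 uncertainty into
  stage-2 posteriors; a joint Bayesian formulation would, at considerable
  computational cost.
- No aggregate-data arms, no inconsistency diagnostics (node splitting),
  no external validation machinery.
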