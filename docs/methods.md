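# Methods

## Scope

`missim` is a simulation laboratory for studying how eight missing-data
strategies behave when the average causal effect (ACE) of a binary exposure
on a continuous outcome is estimated by targeted maximum likelihood
estimation (TMLE). It consists of (i) a synthetic cohort generator, (ii) a
missingness generator driven by missingness DAGs, (iii) the estimation
machinery (stacked ensemble, TMLE and its extension to missing outcomes,
chained-equation multiple imputation with Rubin pooling), and (iv) a
replication engine with simulation performance metrics.

## Data-generating model

Variables are drawn in causal order A → Z1…Z5 → X → Y:

- A ~ N(0, 1): a continuous auxiliary variable (standardized age). It
  predicts three confounders and the exposure, and is available to
  imputation models, but is never part of the confounding adjustment set.
- Z1…Z5 ~ Bernoulli(logit⁻¹(·)): binary confounders (parental divorce,
  antisocial behavior, depression/anxiety, alcohol use, parental
  education). Z1 and Z5 are exogenous; Z2–Z4 depend on A (log-OR 0.3).
- X ~ Bernoulli(logit⁻¹(η₀ + η₁Z1 + … + η₅Z5 + η₆A [+ interactions])):
  the exposure (frequent cannabis use, marginal prevalence 12.4%).
- Y ~ N(θ₀ + θ₁X + θ₂Z1 + … + θ₆Z5 [+ interactions], SD = 1): the outcome
  on the z-score scale. θ₁ = 0.2 is the **true ACE**: no exposure-confounder
  interaction exists, so the conditional effect is constant and
  standardization over any covariate distribution returns θ₁ exactly. The
  package's g-computation check exploits this (it is exact, not merely
  consistent).

Two scenarios share all A/Z draws (per-variable random sub-streams):
*simple* (main effects only) and *complex*, which adds every pairwise,
3-way and 4-way product of {Z1, Z3, Z4, Z5} to the outcome model and the
pairwise products to the exposure model. Z2 never enters an interaction
(its prevalence, 14.6%, is too low to support them).

### Default coefficients and calibration

The non-intercept coefficients are package defaults chosen once: moderate
confounder effects (log-OR / mean-shift 0.4–0.6, parental education
protective at −0.4) and interaction coefficients of 0.4 (pairwise) and 0.3
(higher-order), framed as base values 0.1 / 0.075 inflated four-fold so the
complex scenario genuinely stresses interaction-blind methods. Exposure-model
main effects sit at the lower end of the moderate band (0.4–0.5); this keeps
the influence-curve variance at n = 2000 near 0.072², which by the standard
normal-approximation power calculation gives ≈80% rejection of the no-effect
null at the design effect of 0.2 — a property the study design requires.
All coefficients can be overridden through `PopulationParams` (YAML/JSON
round-trip supported).

Intercepts are never hard-coded. `calibrate_intercept` bisects the expected
marginal prevalence E[logit⁻¹(b + Wβ)] over a fixed 200,000-record covariate
draw (monotone in b, so bisection is exact to the 0.002 tolerance) and
verifies the result with an independent Bernoulli draw allowing 4 binomial
SDs. Targets: Z1 22.1%, Z2 14.6%, Z3 59.9%, Z4 37.2%, Z5 37.7%, X 12.4%. The
outcome intercept centers Y at zero marginally (z-score convention).

## Missingness model

Missingness indicators M_Z2, M_Z3, M_Z4, M_X, M_Y (1 = missing) are drawn
sequentially from logistic models; each model conditions on the fully
observed covariates (Z1, Z5), the variable's own value, the exposure, the
outcome, and all previously drawn indicators. A, Z1 and Z5 stay fully
observed. Two DAGs:

- **m-DAG A** — the outcome does not influence missingness (Y coefficient
  0 everywhere). The ACE is recoverable, and deletion-based methods are
  expected to be (nearly) unbiased.
- **m-DAG B** — the outcome influences missingness in other variables
  (Y coefficient 0.1; never its own missingness). The ACE is not
  recoverable; complete-case-style methods are biased downward because
  high-Y records are preferentially lost, more so in the exposed arm.

Structural coefficients (confounders, exposure) are fixed at 0.9. The
*complex-2* model set adds exposure-confounder products X·Z2/Z3/Z4
(coefficient 0.9) and a Y² term (0 under m-DAG A, 0.08 under m-DAG B; the
M_Y model has no Y² term), stressing imputation models that ignore
interactions and nonlinearities. Y² uses the generated z-score outcome
uncentered, exactly as written in the model.

### Joint calibration

Three deletion fractions are design targets: 50% of records excluded by
complete-case analysis (any of Z2, Z3, Z4, X, Y missing), 40% by the
complete-exposure-and-confounder path, 30% by exposure-only deletion, with
per-variable rates Z2 27.4%, Z3 13.8%, Z4 21.0%, X 30%, Y 20%. Because the
per-variable marginals alone would make the unions far larger (≈65% and
≈72% under independence), the indicators must overlap strongly, and the
overlap is controlled by the coefficients on prior indicators. The
calibrator nests three loops:

1. each model intercept is bisected to its marginal rate using common
   random numbers (the drawn rate is then monotone in the intercept);
2. a single shared dependence coefficient on all prior-indicator terms of
   the M_Z3/M_Z4/M_X models is bisected so the four-indicator union hits
   40% (more overlap ⇒ smaller union, again monotone), re-running loop 1
   inside every evaluation;
3. a second shared coefficient in the M_Y model is bisected (bracket
   allows negative values) so the five-indicator union hits 50%.

Calibration uses a fresh 200,000-record cohort; achieved rates on an
independent 100,000-record cohort land within ~0.5 percentage points of
every target. Infeasible targets raise a `CalibrationError` reporting the
achievable range.

## Estimation machinery

### Stacked ensemble

`cv_stack_fit` fits each base learner per cross-validation fold (5 folds by
default, stratified for binary responses), collects fold-out predictions,
and finds simplex weights minimizing cross-validated risk: non-negative
least squares (normalized) for squared error, simplex-constrained negative
log-likelihood (SLSQP) for binary risk. If the optimized blend is worse
than the best single learner on the same fold-out predictions — possible
after the NNLS normalization — the discrete selector is returned instead,
so the ensemble's CV risk never exceeds the best learner's. Learners that
fail to fit are dropped with a warning; base learners are refit on the full
data for prediction.

The default (trimmed) library is {mean, main-effects GLM, GLM with all
pairwise interactions, elastic net, pruned regression tree}; a fuller
library adds ridge, an additive spline model, a lightly pruned tree and a
random forest. `FAST_LIBRARY` = {mean, GLM} exists for replication-heavy
runs. All learners are scikit-learn estimators.

### TMLE

Continuous-outcome TMLE uses the bounded-outcome device: Y is mapped to
[0, 1] using the observed range of the analysis data (recorded in
diagnostics), Q̄ is fitted as a regression on the scaled outcome and clipped
to [0.005, 0.995], g is truncated to [0.01, 0.99] (configurable), and a
single one-step logistic fluctuation with the two-sided clever covariate is
solved by Newton iteration (bracketing fallback), driving the empirical
score below 1e−10 in practice (guaranteed ≤ 1e−6). ψ̂ is the mean of the
updated prediction contrast, back-scaled; the SE is the influence-curve
sample SD over √n, back-scaled; CIs are normal-quantile.

The extended variant fits an additional observation model
π(X, **Z**) = P(M_Y = 0 | X, **Z**) on all records, enters it in the clever
covariate denominator, estimates the fluctuation on observed-outcome records
only, and averages updated predictions over *all* records. With a fully
observed outcome it reduces exactly to plain TMLE.

### Multiple imputation

`fcs_impute` runs m = 5 chains (default) of 5 cycles of chained-equation
imputation: random-fill initialization from observed margins, then each
incomplete variable in column order is re-imputed from its predictor set.
Imputers:

- binary variables: ridge-penalized logistic regression (penalty 1e−3,
  intercept unpenalized — written here because scikit-learn does not expose
  the coefficient covariance) with coefficients drawn from the asymptotic
  normal approximation before each Bernoulli draw (proper imputation);
- continuous outcome: predictive mean matching, type 1 — donor means at the
  least-squares fit, target means at a posterior coefficient draw
  (normal-inverse-chi-squared), uniform draw among the 5 nearest donors;
- CART: decision tree (min leaf 5, cost-complexity 1e−4), uniform draw from
  the target's donor leaf;
- random forest: 10 bootstrap trees with ⌊√p⌋ split candidates (p = number
  of predictors; 2 in the main-effects setting), uniform draw over the
  pooled multiset of donor-leaf values.

Interaction flavors add product terms *passively*: the 2-way flavor adds
every pairwise product of analysis variables not containing the imputed
variable; the higher flavor adds all 3- and 4-way products of
{Z1, Z3, Z4, Z5}. Products are recomputed from current values each time a
design matrix is built, so they always reflect the latest imputations, and
a product may never predict a variable it contains. The auxiliary A enters
every univariate model. Estimates are pooled by Rubin's rules
(T = W + (1 + 1/m)B, large-sample degrees of freedom, t-based CI; B = 0
falls back to the normal quantile).

## Methods under study

`apply_method` implements the eight strategies exactly as tabulated in the
README. Details worth noting: the missing-indicator method fills masked
confounders with 0 — any constant is equivalent once the indicator is in
the adjustment set for the learners used; MI runs TMLE inside each
completed data set with a common fold seed, so with no missing data all
eight methods collapse to the identical estimate (a tested invariant); the
auxiliary A is used by imputation models only.

## Performance metrics

For estimates ψ̂₁…ψ̂ₙ with model SEs and truth θ: percent relative bias
100(ψ̄−θ)/θ with MC-SE 100·empSE/(θ√n); empirical SE (sample SD) with MC-SE
empSE/√(2(n−1)); model-SE summary √(mean se²) and its percent error
100(modSE/empSE − 1), with a delta-method MC-SE combining the variance of
mean(se²) with the empirical-SE sampling noise. Failed replicates are
counted and excluded, never silently dropped. The rejection rate is the
fraction of replicates with |ψ̂/se| above the normal critical value.

## Numerical and design choices

- **Randomness**: every cohort, missingness draw, fold split and imputation
  chain derives from `numpy` SeedSequence streams keyed by the caller's
  seed; per-variable sub-streams mean the simple and complex scenarios
  share A/Z draws under the same seed, and adding a variable never perturbs
  earlier ones.
- **Nuisance library for bias measurement**: the acceptance computations of
  the deletion-method bias surfaces use main-effects GLM nuisances — the
  correctly specified parametric model under the simple scenario — because
  a very small stack ({mean, GLM}) leaves ~10% weight on the intercept-only
  learner, shrinking the propensity toward the marginal and adding ≈+2
  percentage points of finite-sample bias that has nothing to do with the
  missingness mechanism being measured. The stacked ensemble remains the
  default estimator elsewhere.
- **Desk scale**: the full published-scale grid (2000 replicates × 2000
  records × 6 cells × 8 methods with a 10-learner library) is available but
  slow; the package's reference checks use 500–2000 replicates for
  deletion-method surfaces, 500 for power, and ~60 paired replicates at
  n = 1000 for the MI orderings, sizes at which the qualitative contrasts
  exceed twice their Monte-Carlo SE.
- **Truncation defaults** ([0.01, 0.99] for g and π, [0.005, 0.995] for
  scaled Q̄) protect positivity at a 12% exposure prevalence without
  materially biasing ψ̂; counts of truncated records are reported in
  diagnostics.

## What the generator does and does not emulate

The synthetic cohorts reproduce the motivating study's marginal prevalences,
missingness proportions and deletion fractions, the z-score outcome scale,
the designed effect size and its ≈80% power, and the qualitative missingness
structure of the two DAGs. They do not reproduce the original coefficient
values (unpublished), the longitudinal wave structure (collapsed to summary
binaries), missingness in A/Z1/Z5, or mechanisms where the outcome drives
its own missingness (no method works there). Passing tests therefore
demonstrate correctness of the machinery and the recoverability-driven
qualitative behavior of the methods — small deletion-method bias only when
the outcome does not drive missingness, incompatibility bias of main-effects
MI under interaction-rich generation, attenuation and overconfident pooling
of forest-based imputation — not exact magnitudes from any particular real
cohort.

## Known limitations

- The MI variance estimator is Rubin's; bootstrap-based MI variance is out
  of scope, so model-SE error for MI methods inherits the incompatibility
  overestimation seen in such designs.
- Cross-validated (CV-)TMLE is not implemented; influence-curve SEs are
  mildly anti-conservative with data-adaptive nuisances.
- The calibrators target marginal/union proportions only; higher-order
  overlap patterns (e.g., the joint distribution of exactly which variables
  are missing) are whatever the logistic structure implies.
- Binary outcomes, high-dimensional confounders and longitudinal structures
  are out of scope.
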