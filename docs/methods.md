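# Methods

## Estimands

For a long person-by-wave panel, let A_t indicate being out of paid work
at wave t, M_t the log of OECD-equivalised monthly household income after
housing costs, Y_t GHQ-12 caseness (score ≥ 4), V time-invariant
confounders (gender, ethnicity, education) and L_{t−1} the one-wave-lagged
time-varying confounders (housing tenure, benefits receipt, relationship
status, number of children, SF-12 physical score, region, age and age²,
plus lagged exposure, lagged caseness, lagged MCS and lagged income). The
analysis targets the *short-term* effect: the contrast in Y_t when only
A_t is intervened on, past history left at its natural values.

* TE: E[Y_t^{a=1}] − E[Y_t^{a=0}], income free to respond to the
  intervened exposure within the same wave (the employment→income effect
  is treated as instantaneous).
* CDE: the same contrast with the income pathway blocked — income held at
  the value it would take under employment.
* Percentage mediation: 100 × (TE − CDE) / TE on the risk-difference
  scale. It may be negative or exceed 100 when the arms disagree in sign.
* PAF: 100 × (prev_total − prev_unexposed)/prev_total. Two variants are
  emitted: with the observed weighted caseness prevalence as prev_total
  (reported) and with the model-standardised total prevalence (kept in the
  output for comparison), since either convention is defensible.

Identification assumes no unmeasured confounding beyond V and L_{t−1},
and — as in the causal diagram the package encodes — no exposure-induced
mediator–outcome confounders, because employment affects income within the
same wave.

## Estimator

1. **Exposure weights.** Denominator: pooled logistic model of A_t on V,
   age terms and all lag-1 covariates. Numerator: the *marginal* exposure
   probability. With a marginal numerator the weighted pseudo-population
   breaks the exposure–confounder association for every covariate, which
   is exactly what the SMD balance diagnostic measures; a conditional
   numerator (baseline + lagged exposure, available via
   `fit_exposure_weights(numerator="conditional")`) gives less variable
   weights but leaves its conditioning covariates imbalanced by
   construction, so balance must then be judged only on the remaining
   covariates.
2. **Mediator weights (CDE only).** sw_M is a ratio of two Gaussian
   conditional densities of log income, numerator conditioning on A_t, V
   and age, denominator additionally on the lag-1 covariates, both fitted
   by linear regression with the residual standard deviation estimated by
   maximum likelihood (dof-corrected). Binary poverty receives no separate
   weight: given the poverty line it is a deterministic function of
   income, so weighting it would double-count the same information; it
   enters the CDE outcome model as a covariate instead.
3. **Outcome model.** Weighted pooled logistic regression (own IRLS/Newton
   implementation; score-norm tolerance 1e-8, max 100 iterations, explicit
   separation and rank-deficiency errors naming the culprit column). TE
   covariates: exposure + the full adjustment set (lagged income included,
   concurrent income excluded). CDE adds concurrent log income and
   poverty. The combination of correct weights *or* a correct outcome
   model suffices for consistency (double robustness).
4. **Marginal standardisation.** Every row is predicted twice with the
   exposure forced to each level, all other columns (including concurrent
   mediator columns in CDE mode) at observed values — a natural-value
   controlled contrast; a fixed reference income m* is not imposed. The
   weighted averages of these predictions give the marginal risks, odds
   ratio, risk difference (percentage points) and PAF. Both the marginal
   OR (reported) and the conditional exposure coefficient (in the fit
   object) are available.

### Weight truncation

Off by default. The mediator density ratio is heavy-tailed by
construction (its numerator has a larger residual standard deviation than
its denominator, so the ratio grows exponentially in the squared
residual); in samples of a few thousand persons the resulting extreme
weights produce a small upward finite-sample bias in the CDE — measured at
roughly +0.4 pp at 3 000 persons and provably vanishing (the CDE exposure
coefficient is recovered to three decimals at 60 000 persons). Percentile
truncation at (1, 99) of the combined weight is therefore recommended, and
used by the package's own small-sample studies; it roughly halves the
spread of the percentage-mediation estimate. A residual attenuation of a
few percentage points in percent mediation remains at n = 3 000 and is a
known small-sample property of this estimator class, not removable by
truncation or Hajek normalisation (both were evaluated).

## Multiple imputation

Observations missing more than 9 of the 22 analysis variables are dropped
first (count logged). The chained-equations engine then runs m independent
chains (default m = 20, 10 sweeps each), visiting variables in order of
increasing missingness. Continuous and count variables use type-1
predictive mean matching with k = 5 donors (draws are observed values, so
counts stay integral and income stays positive and skew-robust); binary
variables use logistic draws with coefficients perturbed by their
approximate sampling distribution. Gender, age, wave and number of
children are always predictors; lagged columns are imputed as variables in
their own right. Poverty, caseness, log income and the transition exposure
are re-derived from the completed continuous variables afterwards.
Chain-mean drift beyond 25% raises a warning, not an error. Point
estimates pool across the m completions by Rubin's rule (the mean — applied
to the standardised risks, from which the pooled OR/RD/PAF are recomputed);
interval estimation is delegated entirely to the bootstrap.

## Bootstrap

Persons are resampled with replacement, all waves moving together, from
the *pre-imputation* table; each replicate is imputed once (m = 1, 3
sweeps) and re-estimated, so imputation noise propagates into the
intervals without nesting m full imputations inside each of B replicates
(computationally disproportionate; the scheme is recorded in the
manifest). On complete data the replicate skips imputation and re-uses the
prebuilt design matrices, warm-starting every regression at the
point-estimate coefficients with a capped number of Newton steps (default
2; the one-step variant used by the package's recovery study reproduces
fully converged bootstrap standard errors within 2%). The 95% CI is
point ± 1.96 × bootstrap SE, matching symmetric published intervals;
percentile intervals are stored alongside. Replicates on which an
estimator is undefined (e.g. percentage mediation with a zero TE) are
dropped and counted, with a warning beyond 20%.

## Synthetic panel generator

The generator emulates an annual UK-style household panel: ages 25–64
(baseline ages 25–56 so nine annual waves stay in range), 55.3% women,
education high/medium/low (0.42/0.37/0.21), 12 inert regions. Employment
follows a first-order process with strong persistence (log-odds 3.3) and
feedback from lagged caseness, income, benefits, tenure and physical
health — the time-varying confounding the estimator must remove. Log
income is linear in employment (premium 0.229 on the log scale), education,
gender and age with an AR(1) residual (innovation sd 0.30, persistence
0.6); household composition is generated only to exercise the OECD
equivalisation. Caseness is logistic in current unemployment (direct
effect β_A = 0.380), current log income (β_M = −0.249, optionally scaled
for ages 41–64 to plant effect modification), lagged caseness, gender,
education, lagged PCS and age; the integer GHQ score is then drawn
consistently with the caseness indicator. Default intercepts were
calibrated once against the cohort's descriptive margins: 25.7% of
person-waves out of paid work, mean income near £1 560/month with a mean
loss of ≈ £295/month on a move out of work, caseness prevalence ≈ 18% in
the employed, and structural effects TE ≈ 7.1 pp, CDE ≈ 6.1 pp,
percentage mediation ≈ 14.2%.

`oracle_effects` computes the interventional truth by brute force:
simulate the natural history, then at every wave after the first evaluate
the caseness probability under both exposure levels with the same income
residual (TE) and with the employed-arm income in both arms (CDE),
averaging the analytic logistic risks — so Monte-Carlo error comes only
from covariate sampling and is reported (person-level standard error).

Missingness is injected in two MAR layers driven by always-observed
covariates (gender, age, wave): whole-interview nonresponse (wave 1
exempt, so everyone keeps a baseline record) and per-variable item
nonresponse.

What the generator does *not* emulate: household clustering, survey
weights, attrition by death, variable inter-wave spacing (ages advance by
exactly one year; the square-term adjustment is carried anyway), and
panel-conditioning effects. Passing recovery tests therefore show the
estimator chain is correct under its stated assumptions — not that those
assumptions hold in any particular survey.

## Numerical and design choices

* Incomes ≤ 0 are floored at 1 currency unit/month before logging.
* The poverty line is 60% of the *sample* median (unweighted), computed
  once per input table and recorded in the output metadata; an external
  national median can be substituted upstream.
* The poverty/caseness cut-offs, 25–64 age window, m = 20, B = 1000 and
  the 0.1/0.2 SMD thresholds live in one defaults table
  (`msmediate.config.DEFAULTS`) and are echoed into every manifest.
* A person-wave whose previous wave is absent contributes no outcome row
  (the lag is undefined rather than structurally imputed).
* Transition analyses restrict to the at-risk group (gain: not employed at
  t−1; loss: employed at t−1) and drop the now-constant lagged exposure
  from the adjustment set; the CDE construction is otherwise unchanged.
* Stratified analyses partition observations (age bands and concurrent
  poverty are observation-level); each stratum gets its own weights,
  outcome models, bootstrap and balance report; strata below a minimum
  person count are skipped with a warning.
* Design matrices drop constant columns (recorded), so degenerate strata
  fail soft; genuine collinearity still raises with the aliased column
  named.
* Seeds: one master seed is split deterministically per stage (simulate /
  impute / bootstrap); identical seeds give byte-identical report files
  (no timestamps are written).

## Scaled-down study sizes

The package's own validation studies are sized for a single CPU: the
balance check uses 20 000 persons × 9 waves; the recovery study uses 100
replicates of 3 000 persons with B = 200 bootstrap resamples, m = 5,
(1, 99) truncation and one-step bootstrap refits; the null-mediation check
uses 100 point-estimate replicates. These sizes are the package's choice
of a demonstrative scale; the estimator code is the same at any size.

## Known limitations

* The CDE mediator weights are heavy-tailed; below ~5 000 persons expect
  a small attenuation of percentage mediation (see Weight truncation).
* Percentage mediation is a ratio and unstable when the TE is near zero;
  undefined replicates are dropped and counted rather than extrapolated.
* The imputation engine is single-level (no household/person random
  effects) and region is neither imputed nor used as an imputation
  predictor (rows with missing region should be dropped upstream).
* The pooled logistic outcome model reports no analytic (sandwich)
  variances; all uncertainty comes from the cluster bootstrap.
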