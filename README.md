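# msmediate

Causal mediation analysis of the short-term effect of unemployment on
common mental disorder (CMD), with household income as the mediator, using
double-robust marginal structural models.

## The scientific problem

Unemployment worsens mental health, and it also lowers income — which
itself affects mental health. For policy it matters how much of the
unemployment effect operates *through* income (income-protection policies
can offset it) versus *directly* (they cannot). With longitudinal survey
data this is a time-varying-confounding problem: past mental health, past
income and past employment all influence current employment, so ordinary
regression adjustment fails.

`msmediate` implements the standard epidemiological answer for a
person-by-wave panel in which the exposure A is being out of paid work,
the mediator M is (log) OECD-equivalised household income after housing
costs, and the outcome Y is GHQ-12 caseness (score ≥ 4):

* **Total effect (TE)** — stabilised inverse-probability-of-treatment
  weights `sw_A = P(A_t = a) / P(A_t = a | V, L_{t-1})` are fitted from a
  logistic exposure model on all time-invariant confounders V (gender,
  ethnicity, education) and one-wave-lagged time-varying confounders
  L_{t-1} (tenure, benefits, relationship, children, physical-health
  score, region, plus lagged employment, caseness, MCS and income). A
  weighted pooled logistic outcome model with the same adjustment set is
  then standardised by g-computation: every row is predicted with A forced
  to each level and the weighted average risks give the marginal odds
  ratio and the absolute risk difference in percentage points.
* **Controlled direct effect (CDE)** — mediator weights
  `sw_M = f(M_t | A_t, V) / f(M_t | A_t, V, L_{t-1})` (Gaussian density
  ratio on log income) are multiplied in, and concurrent log income and
  poverty enter the outcome model, blocking the income pathway.
* **Percentage mediation** — `100 × (TE − CDE) / TE` on the risk-difference
  scale, the attenuation of the total effect once the income path is
  blocked.
* **Population attributable fraction** —
  `100 × (prevalence_total − prevalence_unexposed) / prevalence_total`.

Inference is by cluster bootstrap (persons resampled with all their
waves; 95% CI = point ± 1.96 × bootstrap SE). Missing data are handled by
chained-equations multiple imputation (predictive mean matching for
continuous/count variables, logistic draws for binary ones), after
dropping observations missing more than 9 of the 22 analysis variables;
poverty and caseness are dichotomised after imputation. Covariate balance
is diagnosed with standardised mean differences before/after weighting
(0.1 / 0.2 thresholds).

Because the motivating cohort (a UK household panel) is access-restricted,
the package ships a synthetic panel generator with the same causal
structure and *known* interventional effects, so every stage is testable
against ground truth. See `docs/methods.md` for the model, assumptions and
numerical choices.

## Worked example

```python
from msmediate import MediationMSM, SimParams, oracle_effects

params = SimParams(n_individuals=20_000, seed=17)   # defaults: 9 annual waves
print(oracle_effects(params, n_mc=200_000).oracle_TE_rd)  # structural truth: 7.10

model = MediationMSM.from_simulation(params)
res = model.fit(n_boot=200, seed=17, truncate=(1.0, 99.0))
print(res.summary())
```

```
Marginal structural mediation analysis (weighted pooled logistic outcome model)
mode: full   persons: 20000   observations: 160000   bootstrap B: 200
------------------------------------------------------------------------------
                                        Total effect           Direct effect
Odds ratio                          1.50 (1.44-1.56)        1.43 (1.36-1.49)
Risk difference (pp)                7.02 (6.30-7.75)        6.17 (5.33-7.00)
Prevalence unexposed (%)         19.16 (18.82-19.49)     19.33 (18.96-19.69)
PAF (%)                                         9.31                    8.18
% mediation                       12.22 (5.69-18.74)
------------------------------------------------------------------------------
max post-weighting SMD: TE 0.042, CDE 0.115
```

Read: being out of paid work raises CMD prevalence by 7.0 percentage
points in the same wave (marginal OR 1.50); blocking the income pathway
leaves 6.2 points, so income mediates about 12% of the total effect
(bootstrap 95% CI 6–19%). The generator's oracle values for these
parameters — printed above: TE = 7.09 pp, CDE = 6.09 pp, mediation =
14.2% — all lie inside the intervals. Exposure-weight balance is excellent
(lagged employment starts near SMD 1.9 unweighted and ends below 0.05);
the combined mediator weights leave one income covariate slightly above
the 0.1 line, which is typical for controlled-direct-effect weighting.
`truncate=(1.0, 99.0)` clips the heavy-tailed mediator density-ratio
weights at their 1st/99th percentiles (recommended; see
`docs/methods.md`).

Transition analyses (`model.fit(mode="transition-loss")`, restricted to
those at risk), stratified analyses
(`model.fit_stratified("age-band")` for gender / education / age band /
concurrent poverty) and a complete-case mode mirror the full pipeline.

From the shell:

```bash
msmediate simulate --config config.yaml --out data/
msmediate run --config config.yaml --out results/ --bootstrap 1000 --imputations 20
```

`run` writes `table1.csv` (TE/CDE/PAF/% mediation), `table2.csv`
(transitions), `table3.csv` (strata), `balance_*.csv`, a `manifest.json`
echoing the full effective configuration and seeds, and a `run.log` with
per-stage row counts. Identical seeds give byte-identical outputs.

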