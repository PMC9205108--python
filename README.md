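# fact8d

A discrete-choice-experiment (DCE) valuation pipeline and utility scoring
engine for the **FACT-8D**, the eight-dimension health-state
classification derived from the FACT-G cancer quality-of-life
questionnaire.  It is written for health economists and outcomes
researchers who need either end of the valuation workflow:

- **scoring** — convert FACT-G item responses (GP1, GP2, GP4, GF1, GF5,
  GS2, GS3, GE1, GE6, each 0–4) into utilities with a value set; the
  published Canadian value set is packaged;
- **valuation** — run the estimation pipeline that produces such a value
  set: partial-profile DCE design, survey-weighted conditional logit,
  monotonicity constraining, and QALY anchoring, with a synthetic-data
  generator that emulates the study so everything runs without any
  respondent-level data.

## The model

Respondents repeatedly choose between two health states, each lived for
`t ∈ {1, 2, 5, 10}` years.  Utility is QALY-parameterized,

    V = α·t + Σ_dl β_dl · x_dl · t,

with i.i.d. extreme-value errors, so choices follow a conditional logit
on within-pair differences.  `α` is the utility of a life-year in full
health; each dimension-level dummy enters multiplied by duration, which
pins the utility of zero remaining life-years at 0 and makes proportional
time trade-offs constant.  Fitting is exact Newton maximum
(pseudo-)likelihood with cluster-robust (sandwich) covariance over
respondents.  Non-monotone level coefficients are collapsed and refit
until the profile is consistent, and the marginal rate of substitution
with duration converts coefficients into decrements, `w_dl = −β_dl / α`.
A state's utility is then `1 − Σ_d w_{d,l(d)}`; the Canadian set scores
full health at 1 and the worst describable (PITS) state at −0.65.

## Worked example

Score FACT-G responses with the packaged Canadian value set:

```
python analysis/06_score_factg.py
```

```
 GP1  GP2  GP4  GF1  GF5  GS2  GS3  GE1  GE6  utility
   0    0    0    4    4    4    4    0    0    1.000
   1    0    1    4    3    4    4    0    0    0.946
   2    1    2    4    4    4    4    2    2    0.525
   4    4    4    0    0    0    0    4    4   -0.652

scored 4/4 rows; utility range [-0.652, 1.000], mean 0.455
```

The first row is full health (note the positively phrased items GF1, GF5,
GS2, GS3 score 4 when there is no problem): utility 1.  The last row is
the PITS state, worse than dead at −0.652.  The same computation is
available as a library call (`fact8d.score_factg`) and a console command
(`fact8d score --responses ... --out ...`).

The full valuation cycle on synthetic data runs either as the numbered
analysis scripts,

```
python analysis/01_build_design.py      # 30 blocks x 16 partial-profile sets
python analysis/02_simulate_cohort.py   # 1,582 respondents, skewed demographics
python analysis/03_survey_weights.py    # 2%-rule flags + raking (IPF)
python analysis/04_fit_models.py        # Models 1-3, LR/AIC/BIC, comparisons
python analysis/05_derive_value_set.py  # MRS anchoring -> value set
python analysis/06_score_factg.py       # apply the value set
```

or as one call (`fact8d pipeline --seed 1 --out results/run`, or
`fact8d.run_pipeline(PipelineConfig(seed=1))`).  A typical
`04_fit_models.py` run prints, for example,

```
Model 1 (unweighted):  LL=-15479.90  k=33  AIC=31025.80  BIC=31293.48
Model 2 (raked):       LL=-15633.63  k=33  AIC=31333.26  BIC=31600.94
Model 2 monotonicity violations: 10
  - sleep level 2: coefficient +0.0142 >= 0 (worse level implies utility gain)
  ...
Model 3 (constrained): LL=-15649.65  k=23  AIC=31345.31  BIC=31531.87  (2 merge rounds)
```

— the weighted fit shows the sign and ordering inconsistencies the
constraint loop then collapses (here to 23 parameters), after which
`05_derive_value_set.py` anchors the coefficients and reports the derived
decrement table and its distance from the generating truth.

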