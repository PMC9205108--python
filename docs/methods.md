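# Methods

## The valuation problem

The FACT-8D is a multi-attribute utility instrument for cancer-specific
quality of life: eight dimensions (pain, fatigue, nausea, problems
sleeping, problems working, problems with support, sadness, worry about
one's health worsening), each with five severity levels mapped from nine
FACT-G items.  A *value set* attaches a utility decrement `w_dl` to every
dimension `d` and level `l`, anchored so that full health scores 1 and
being dead scores 0; the utility of a described state is

    U = 1 − Σ_d w_{d, l(d)}.

This package implements the whole valuation workflow that produces such a
value set from a discrete choice experiment (DCE), and the scoring
algorithm that applies one (the published Canadian set is packaged).

## Random-utility model and estimation

Respondent `i` in choice set `s` sees two alternatives `j ∈ {A, B}`, each
a health state `x` lived for `t ∈ {1, 2, 5, 10}` years.  Deterministic
utility is QALY-consistent:

    V_isj = α·t_isj + Σ_dl β_dl·x_isjdl·t_isj

so every dimension-level dummy enters multiplied by duration: a state
lived zero years has zero utility, and the fraction of remaining life a
respondent would trade for a health improvement does not depend on the
remaining horizon (constant proportional trade-off).  `α > 0` is the
utility of one life-year in full health; level 1 of each dimension is the
reference (`β_d1 = 0`), giving 1 + 8×4 = 33 free parameters.

Errors are i.i.d. type-I extreme value (Gumbel), so the choice
probability is the logistic function of `V_A − V_B` and the model is a
conditional logit — equivalently a binary logit on differenced regressors
with no intercept.  The simulator uses the same Gumbel errors the
estimator presupposes; a normal-error (probit) variant was deliberately
not used because the fitted model is the logit.

Estimation is Newton–Raphson with analytic gradient and Hessian from a
zero start, converged when the gradient max-norm falls below 1e-6.  The
Cholesky factorization of the information matrix doubles as the
identification check: a design with too few distinct choice sets (e.g. a
single 16-set block against 33 parameters) fails with a clear error
rather than producing garbage covariance.  Survey weights multiply each
respondent's log-likelihood contribution (pseudo-maximum likelihood).
The covariance is always the cluster-robust sandwich with clusters =
respondents, so the 16 repeated choices of one person are never treated
as independent; no small-sample correction is applied, which makes the
estimator collapse exactly to HC0 when every cluster has one observation.
AIC = 2k − 2LL; BIC uses the number of choice-set observations as its
sample size (the convention is configurable because none is canonical for
clustered pseudo-likelihoods).

## Monotonicity constraining

An unconstrained fit can violate severity ordering two ways: a positive
level coefficient (a worse level implying a utility *gain* over the
reference) or a reversed adjacent pair (a worse level less disliked than
a milder one).  The constraint loop alternates fit → detect → merge:
positive groups adjacent to the reference merge into the reference
(coefficient pinned at 0); reversed adjacent pairs merge into one shared
group.  All violations found in one round are applied together; within a
dimension, chains of reversals are resolved mildest pair first, the
remainder left to the next round.  The loop stops when a fit is
violation-free (so it is idempotent on monotone fits) or errors after
`max_rounds` (default 10) with the residual list.  Because every merge
restricts the parameter space, the constrained log-likelihood can never
exceed the unconstrained one.  Small *negative* coefficients are never
merged automatically — only sign and ordering violations trigger merges —
but a caller can force an exact collapsing pattern (e.g. the published
23-parameter pattern) via `forced_spec`.

## Anchoring

Coefficients become decrements through the marginal rate of substitution
with duration: `w_dl = −β_dl / α`, the fraction of remaining life-years a
respondent would give up to avoid that level.  Anchoring requires
`α > 0`; reference-merged levels get decrement 0 and pair-merged levels
share a value, so the derived set is monotone by construction.  Decrement
tables are exported at 3 dp but kept at full precision internally; the
derived decrements always come from unrounded coefficients.

The packaged Canadian value set stores the published table verbatim.  The
published pain row (0.077/0.187/0.384) is *not* −β/α of the published
constrained pain coefficients (which give 0.057/0.197/0.407); the other
rows are consistent at 3 dp.  The scoring fixture follows the published
table and the discrepancy is documented rather than resolved.  For the
same reason the published constrained model's printed AIC/BIC (which are
not 2k − 2LL of its printed LL and k) and its printed LR statistic are
not reproduced by this package.

## Synthetic data: what it emulates, what it does not

No respondent-level data are deposited, so every stage runs against a
synthetic study designed to match the published structure:

- **Design** — 16 binary choice sets per respondent; exactly five of the
  nine attributes (duration plus four dimensions by default) differ
  within a set; durations from {1, 2, 5, 10}; A/B presentation
  randomized; attribute order fixed.  The original design matrix is
  unpublished, so the generator performs randomized level-balanced search
  (best of 30 candidate blocks by squared deviation of level frequencies
  from uniform) rather than D-efficient optimization; an external design
  CSV can be supplied instead.  The pipeline pools 30 blocks (480
  distinct sets, respondents cycling over blocks): one block's 16
  distinct regressor rows cannot identify 33 parameters.
- **Cohort** — 1,582 respondents.  Sex, age group and region are sampled
  quota-exact against (renormalized) census margins by largest-remainder
  rounding, mirroring the quota-sampled survey.  Language, education and
  self-rated health are drawn at the achieved study-sample proportions,
  reproducing the published over-representation of English speakers and
  higher education so the 2-percentage-point rule flags exactly those
  variables and raking has real distortion to correct.
- **Choices** — Bernoulli draws at the closed-form logistic probability
  under "true" preferences set to the published constrained coefficients
  (α = 0.366).  A configurable fraction of respondents (default 81/1582,
  the published rate) abandons the survey partway, completing a uniform
  1–15 sets, which exercises the at-least-one-choice-set inclusion rule.

The generator draws homogeneous preferences: no latent classes, no
attribute non-attendance, no panel correlation beyond the clustering the
estimator accounts for, and choices independent of demographics.  Passing
recovery tests therefore show the estimator is correct under its own
assumptions, not that the published estimates would be recovered from
real respondents, whose heterogeneity the published study itself handled
only post hoc.

All randomness flows from one seed through
`numpy.random.SeedSequence(seed).generate_state`, one child stream per
stochastic stage.

## Weighting

Representativeness is assessed per variable by the maximum absolute
deviation of sample from population proportions (flag at ≥ 2 percentage
points) and a goodness-of-fit χ² with expected counts from the targets.
The published χ² values are not reproduced: whether the study tested
against rounded proportions or joint distributions is unknown.  Raking is
classical IPF on marginal targets: multiply weights by target/observed
ratios, cycle over variables until every raked margin matches within
1e-6 (default), normalize to sum to n.  One-variable raking reduces
exactly to post-stratification.  No trimming by default; a cap is
available.  Weighted margins of non-raked variables are reported, never
adjusted.  Printed census margins for region and education do not sum to
1 (rounding); the loader renormalizes per variable.

## Numerical choices and scale

- Gradient tolerance 1e-6 (max-norm); step-halving line search keeps the
  Newton ascent monotone.
- Utilities and decrements are full precision internally; 3-dp decrement
  / 2-dp utility rounding only at export.
- FACT-G mapping: strict missing policy (refusal naming the item; no
  imputation); support takes the better of GS2/GS3, and when one of the
  two is missing the strict policy refuses rather than guessing.
- Exhaustive scoring audits enumerate all 5⁸ = 390,625 states
  vectorized (≈3 MB), checking the [PITS, 1] range and that worsening a
  single dimension never raises utility.
- Tests run the estimation stack at 400 respondents × 12 blocks (seconds)
  and the recovery checks at the full 1,582 × 16 study scale; the
  acceptance script repeats the study-scale cycle from scratch.

## Known limitations

- The recovery of individual decrements at the study scale is limited by
  sampling error: with robust coefficient SEs around 0.007 (matching the
  published magnitudes), each derived decrement carries an SE near 0.02,
  so the worst of ~30 decrement errors is typically 0.03–0.05 even under
  a correctly specified homogeneous simulator.
- Mixed logit and latent-class extensions, joint-margin calibration,
  replicate-weight variance, and D-efficient design construction are out
  of scope.
- The full FACT-G wellbeing subscales are not scored; only the nine
  mapped items are consumed.
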