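# Methods

## The measurement model

Each respondent-wave is classified from four items: worry about catching
COVID-19 in the past three weeks (yes/no), taking precautions (yes/no),
whether the precautions make the respondent feel safer (five-point extent
scale), and the extent to which quality of life is reduced by the worry and
by the precautions (two five-point extent items).

Rule order, applied per record:

1. worry item missing → **unclassifiable**;
2. not worried → **unworried**, whatever the other answers;
3. worried and (no precautions, or precautions-missing) → **dysfunctional**;
4. precautions but the feel-safer item missing → **dysfunctional** (a
   non-answer is treated as the absence of felt benefit, matching the
   published table's placement of that cell);
5. precautions but feel-safer below the positive cut → **dysfunctional**;
6. combined quality-of-life impact "some or strong on either item" →
   **dysfunctional**;
7. combined impact missing → **dysfunctional** by default, or
   **unclassifiable** under the `missing_qol_policy="unclassifiable"`
   switch;
8. otherwise (all three functional conditions hold) → **functional**.

Every record carries a `rationale_code` naming the rule that fired, so each
cross-tab cell's membership is auditable.

Two ordinal cuts parameterise the scheme (`DichotomyConfig`):

* `feel_safer_positive_levels`, default {moderately, quite a bit, very
  much}. The cut must be upward-closed. The source tables are ambiguous
  about where this cut sat (one table implies almost all precaution-takers
  "felt safer", while the text statistic for moderately-or-above is 81%);
  both readings are supported via this parameter and the default follows
  the text statistic.
* `qol_low_levels`, default the bottom two levels {not at all, a little}
  ("none or little effect"); must be downward-closed.

The combined quality-of-life dichotomy is: *none-or-little* iff both items
are low; *some-or-strong* iff at least one item is high (one high answer
decides even when the other is missing); *missing* otherwise.

The simplified two-way variant ignores precautions entirely: among the
worried, quality of life reduced by worry → dysfunctional, else functional.
It is a strict relaxation, so every fully-functional respondent is also
simplified-functional (property-tested).

## Derived indices

* **COVID-impact score**: sum of eight binary adversity indicators (own
  work loss, household job loss, unpayable bills, food access, medication
  access, lost accommodation, close person hospitalised, close person
  died), range 0–8. A formative count, not a latent construct; having had
  COVID-19 is kept as a separate predictor. Missing indicators count as 0
  with a per-record flag.
* **Emotion score**: six extent items (anxiety, anger, loneliness,
  happiness, worthwhile, satisfied) coded 1–5 with the three positive items
  reverse-keyed, summed to 6–30 (higher = worse). Missing any item makes
  the score missing; no imputation. Reliability is reported as Cronbach's
  alpha, `(k/(k−1))(1 − Σ item variances / total variance)` with ddof = 1;
  zero total variance raises rather than returning a value.
* **Re-engagement score**: wave-3 minus wave-2 totals of three behaviour
  items (socialising outside the household, walking/relaxing outside,
  leisure travel) coded 0–4 on their frequency scale. 0 = no change,
  negative = less activity after restrictions eased. The source is
  ambiguous between a single-item and summed-item wave-2 baseline; the
  sum-vs-sum reading is implemented, with per-activity differences emitted
  so either can be reconstructed.
* **Risk-perception recodes**: likelihood / control / severity pass through
  as 1–5 integer codes in codebook level order; any monotone relabelling of
  levels leaves downstream rank order unchanged.

## Quota weighting

Cell mode computes exact post-stratification weights per gender × age cell
(target share / sample share), erroring on empty cells with positive
targets. Raking runs iterative proportional fitting on the two margins to a
max margin error of 1e-8 (cap 100 sweeps). Weights are rescaled to a
configurable normalization total; the default preserves the sample size,
but published weighted totals need not equal n, hence the switch. No
variance estimation under weighting is attempted.

## Transitions

Linked panelists classifiable in both waves enter a 3×3 count matrix in
fixed group order (unworried, functional, dysfunctional); rows are
normalised to probabilities (all-NaN where a row is empty) and the
stability share is trace/n. Respondents lost to attrition or unclassifiable
in either wave are excluded and counted separately.

## Association models

Model fitting is delegated to statsmodels behind a declarative
`ModelSpec`: multinomial logit (reported as relative-risk ratios against a
chosen reference group), negative binomial (exponentiated mean multipliers
plus dispersion theta = 1/alpha), Poisson and linear (raw coefficients).
Listwise deletion throughout, with the used n always reported; significance
stars use strict thresholds (\*\*\* p<0.001, \*\* p<0.01, \* p<0.05).
Attitudinal covariate blocks (deterrence, legal legitimacy, police
legitimacy, social norms, expressive function of the law) are scored as the
standardized first principal component of the z-scored items, sign-aligned
so the mean loading is positive.

Numerical choices:

* When the negative-binomial BFGS line search stalls with a numerically
  zero gradient (dispersion at its boundary), the fit is accepted; a larger
  residual gradient triggers a Nelder–Mead retry before an explicit
  convergence error is raised. If the joint Hessian is singular at the
  boundary, standard errors are recomputed conditional on the estimated
  dispersion via a GLM refit.
* Rank-deficient designs raise an error naming the aliased columns rather
  than silently dropping terms.
* Weighted fits are available for the Poisson (frequency weights) and
  linear (WLS) families; the multinomial and negative-binomial estimators
  do not accept weights and say so. Default fits are unweighted.

Reference-category switches are exactly consistent: refitting the
multinomial with a different reference yields ratio estimates that are
reciprocals/quotients of the originals (tested to 1e-6).

## Synthetic panel generator

The generator emulates the study conditions: 1100 wave-2 respondents in ten
UK cities, completely-at-random attrition to 1019 at wave 3, wave-2 group
shares equal to the published classification counts (401/203/487 of 1091),
and a row-stochastic transition kernel with diagonal 0.71 whose off-diagonal
mass is split proportionally to the destination groups' marginal shares.

Group membership follows a multinomial logit on having had COVID-19 and the
0–8 impact score, using the published relative-risk ratios (2.439 and 1.012
for had-COVID; 0.979 and 1.465 for the impact score, functional and
dysfunctional vs unworried). Intercepts are solved numerically on the
realized covariates so marginal group shares match the configured
proportions, which makes parameter-recovery tests well-specified-model
coverage checks. A `null_effects` switch zeroes every group effect for
type-I-error simulations.

Questionnaire answers are then drawn *inside the cell that defines each
group* (e.g. functional respondents always take precautions, feel safer,
and report low impact on both quality-of-life items), so the classifier
recovers the latent group with zero error by construction — label fidelity
is a generator invariant, not an estimate. Dysfunctional respondents are
allocated across their four defining cells in the published proportions
(34:5:10:438).

Emotion items come from a one-factor latent normal model: item_i = mu_g +
sd·(√r·person + √(1−r)·noise), discretized by rounding and clipping to 1–5.
The latent group means are solved with Brent's method on the closed-form
discretized mean so that expected group score totals equal 14.312 × {1,
0.913, 1.164} exactly after discretization. Inter-item correlation r = 0.62
and item sd = 0.8 were chosen once to target an internal consistency near
0.88 (realized alpha ≈ 0.89 at n = 1100) and moderate overdispersion.
Risk-perception items use the same latent-normal discretization with group
means ordered so the dysfunctional group perceives the highest likelihood
and severity and the lowest control. Compliance behaviours are
Binomial(4, p) frequencies with p = 0.15 in wave 2 and 0.35 in wave 3,
independent of group. Experience indicators are independent Bernoulli draws
with configurable marginals (defaults between 0.4% and 14%, plausible
mid-2020 UK adversity rates; the source reports no numeric marginals).

What the generator does **not** emulate: item nonresponse beyond the
structurally missing feel-safer/quality-of-life cells, city-level or
household structure, informative attrition, measurement error in the
classification items, or any dependence of compliance on worry group.
Passing recovery tests therefore demonstrates that the estimators recover
the generating process when the measurement model is correct — not that the
published real-data coefficients are reproducible, which they are not
without the unit-record data.

## Test problem sizes

Calibration checks bounded by sampling error run on a 10,000-respondent
panel (3-binomial-SE bands). Parameter recovery uses 200 replicates at the
study's model n of 1058: multinomial CI coverage of the two generating
relative-risk ratios is required to be ≥90%, the negative-binomial group
multipliers must be recovered within 3 single-fit standard errors on the
mean across replicates, and under the null generator the pooled Wald
rejection rate must stay ≤7% at nominal 5%. The published-count fixture
checks are exact.

## Known limitations

* The default codebook (item names, level labels) is a reconstruction; real
  exports must be mapped onto it via the alias table.
* The published weighted totals cannot be reproduced because the weight
  construction details are not public; the weighting module is validated
  against closed-form and IPF oracles instead.
* No multiple imputation, latent-class alternative to the rule-based
  scheme, or >2-wave Markov machinery.
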