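# Methods

`radq` estimates an optimal two-stage dynamic treatment regime (DTR) from
SMART-style trajectory data with the design of the STEP-BD acute-depression
randomized (RAD) pathway, and ships a synthetic cohort generator with known
generative truth so that every stage of the pipeline can be validated
without access to subject-level trial data.

## Data model and design

One trajectory per subject: baseline covariates X1 (demographics, bipolar
type, prior-episode status PRONSET, symptom subscales SUMD0 ∈ [0, 22] and
SUMM0 ∈ [0, 16], nine side-effect indicators), stage-1 treatment
A1 ∈ {Bupropion, Paroxetine, placebo}, proximal outcomes X2 (SUMD1, SUMM1,
responder status R), stage-2 treatment A2 where applicable, and the distal
outcome Y = SUMD at week 12, coded so lower is better.

A responder improved by at least 50% on SUMD (the boundary is inclusive —
"at least") without emergent (hypo)mania.  Feasible sets mirror the trial:
every arm at stage 1; at stage 2 responders are not re-randomized (empty
set), drug non-responders escalate their own drug (singleton), and only
placebo non-responders are randomized between the two high-dose drugs.
The load-time validator enforces instrument ranges and these feasibility
constraints.

## Q-learning

Linear working models

    Q2(h2, a2) = h20'β20 + a2 · h21'β21
    Q1(h1, a1) = h10'β10 + a11 · h11'β11 + a12 · h12'β12

with a2 = 1 for high-dose Bupropion, a11/a12 dummies for Bupropion /
Paroxetine against placebo, PRONSET1 = remission, PRONSET2 = (hypo)manic
(mixed is the reference).  Backward induction: (i) OLS of Y on the stage-2
design over placebo non-responders only — the only subjects randomized at
stage 2; (ii) pseudo-outcome Ŷ = min_a2 Q̂2 for those subjects and the
observed Y for everyone else (dose escalation is deterministic, not a
decision); (iii) OLS of Ŷ on the stage-1 design over all subjects.  With
multiply imputed data the rule is the argmin of the imputation-averaged
Q-functions.

Ties in the argmin break toward placebo at stage 1 (then Bupropion over
Paroxetine) and toward high-dose Paroxetine at stage 2; ties occur with
probability zero under continuous covariates, so the choice only pins down
reproducibility.  Histories with missing model fields are rejected at
decision time rather than imputed on the fly — imputation happens before
fitting, not at deployment.

The default ("reported") term sets are the fitted forms of the RAD
analysis: h20 = (1, SUMM1, SUMD1, SIDE3), h21 = (1, SUMM1, SIDE3),
h10 = (1, AGE, SUMM0, SUMD0, PRONSET1, PRONSET2) and h11 = h12 =
(1, AGE, PRONSET1, PRONSET2).  The stage-1 interaction blocks use AGE —
the published coefficient table and the published age-driven decision rule
both carry A1k×AGE terms, which we take as authoritative over a textual
h11 = (1, SUMM0, …) variant.  A caution on the published point estimates:
plugged into the argmin they recommend Bupropion exactly when SIDE3 = 0
and SUMM1 < 1.18/0.77 ≈ 1.53, and the stage-1 Bupropion-vs-placebo
contrast for (hypo)manic-onset subjects changes sign near age 42, so
rule renderings from rounded coefficients are boundary-sensitive.

## Synthetic cohort generator

The generator is the package's study population; its defaults are fixed to
the trial's printed summaries and are not experiment knobs.

* **Baseline covariates** are mutually independent.  Categorical and
  binary variables use the printed level frequencies.  Numeric baselines
  (AGE, SUMD0, SUMM0) are truncated normal on the printed range with the
  underlying (μ, σ) solved numerically so that the *truncated* mean and SD
  equal the printed ones (a two-parameter moment match via least squares).
  Only marginals are printed, so no correlation structure is claimed.
* **Stage-1 allocation** defaults to the empirical arm frequencies
  (0.233, 0.255, 0.512) — the protocol ratio is not stated.
* **Proximal outcomes.**  SUMD1 and SUMM1 are linear in baseline terms and
  treatment dummies plus Gaussian noise (defaults: antidepressants lower
  SUMD1, slightly raise SUMM1, and are less effective after a (hypo)manic
  onset), censored to the instrument ranges.  Intercepts are calibrated by
  root-finding so that the censored marginal means equal the printed 4.49
  (SUMD1) and 0.95 (SUMM1) over a large internal reference sample; the
  censored-normal mean is evaluated in closed form.  Censoring, not
  truncation, is the right mechanism here: the printed SUMM1 marginal
  (mean 0.95, SD 1.30 on [0, 6.75]) has coefficient of variation above 1,
  which no truncated normal attains but a floor-censored score does.
  Emergent (hypo)mania is Bernoulli with a logistic model in SUMM0 and the
  treatment dummies; R then applies the responder rule.
* **Distal outcome.**  Placebo non-responders draw Y from a linear model
  whose default coefficients are the fitted stage-2 Q-function of the RAD
  analysis, so parameter-recovery experiments are anchored to printed
  numbers; responders and escalation arms use separate linear branch
  models (package choices).  Noise SD 2.5, censored to [0, 22].
* **Missingness.**  MAR: each maskable column's missingness propensity is
  logistic in the always-observed AGE and stage-1 arm (slopes 0.02/year
  and 0.30 for active drug), with the intercept solved per column to hit
  the requested marginal rate; an MCAR switch zeroes the slopes.  The
  default profile uses 0.285 on SUMD1/SUMM1/SUMD2 — echoing the 104/365
  subjects lost by stage 1 — and 0.05–0.10 on the socio-demographic and
  side-effect items; exact per-variable rates are not printed and are
  config parameters.  Treatment columns and responder status stay
  observed by default.
* **Truth oracle.**  Because the law is known, any regime's value is
  computed by simulating covariates and stage-1 noise forward under forced
  decisions and integrating the final noise in closed form; the returned
  Monte-Carlo SE reflects covariate variation only.

Dedicated experimental designs, also part of the generator module: an
all-placebo-non-responder cohort whose outcome is exactly linear in the
stage-2 coefficients (stage-2 recovery and selection studies; SUMD1/SUMM1
drawn from their printed marginals independently of baseline, so every
baseline candidate is null by construction); a stage-1 design whose
regression targets are exactly linear in the published first-stage
coefficients (the pipeline's stage-1 estimand E[min_a2 Q2] is not linear
under any generative choice, so recovery is checked on the regression
step itself); and a fully discrete toy cohort for exact
dynamic-programming comparisons.

## Multiple imputation

Chained equations with one conditional model per incomplete column:
predictive mean matching for continuous columns (type-1 matching, 5
donors, flat-prior posterior draw of the linear model via the SVD),
logistic regression for binary columns and multinomial-logistic for
three-level categoricals (both refit on a bootstrap resample of the
observed rows per draw, a robust way to propagate parameter uncertainty
that avoids separation failures).  Predictors per conditional model are
chosen by forward stepwise BIC on the complete cases — the same criterion
the Q-model selection uses.  Chains initialize from random observed
values, run 10 sweeps in least-missing-first order, and are independent
across the m imputations.  Defaults m = 25, 10 sweeps, 5 donors; none of
these is dictated by the analysis being reproduced, and the imputation
manifest flags them.  A masked second-stage treatment is filled
feasibility-aware (deterministic escalation; empirical Bernoulli on the
placebo arm).  Observed cells are never altered.

## Model selection

Forward stepwise search minimizing the Gaussian-profile BIC
n·log(RSS/n) + k·log n averaged over the m imputed datasets, on the rows
entering each stage's regression.  Stage 2 is selected first; stage 1 is
then selected with the stage-2 spec fixed, recomputing pseudo-outcomes
per imputation.  The base model is intercept plus treatment dummies
(every reported fitted model contains them); moves add a candidate's main
effect, or its interaction with a treatment dummy once the main effect is
present (weak hierarchy — consistent with every reported model, which has
e.g. a SUMD1 main effect without an interaction).  Categorical candidates
move as dummy blocks.  Equal-BIC ties (tolerance 1e-9) break toward the
earlier candidate in the printed predictor-table order.  Stage-2-only
variables (SUMD1, SUMM1) are inadmissible at stage 1; treatment-1 dummies
are excluded from the stage-2 pool because they are identically zero on
the placebo subset.  The starting model of the forward search is not
stated by the analysis being reproduced; intercept + treatment dummies is
this package's documented choice.

## Bootstrap inference

Nonparametric subject-level bootstrap.  Term specs (and, with
missingness, the conditional imputation models) are frozen before
resampling; each replicate re-runs imputation (reduced m, default 5) and
both Q-learning stages, and percentile intervals use the order-statistic
convention (⌈αB⌉-th and ⌈(1−α)B⌉-th replicate), which degenerates to
min/max at B = 2.  Selection is *not* redone inside replicates: the
estimand is the coefficients of the single selected model.  Replicates
whose resample cannot support the stage-2 fit are dropped and counted;
more than 10% dropped is a hard error.

Stage-1 estimands are non-regular (the pseudo-outcome's min(0, c) kink).
The correction applied here is soft-thresholding of the fitted contrast:
c ← c·(1 − λ/c²)+ with λ = Var̂(c)·z²_{1−α/2} per subject, before the
stage-1 refit.  The exact correction used in the original analysis is not
recoverable from its description, so both `soft_threshold` and `none` are
exposed and the output metadata says which ran.

## Regime values

Normalized (Hájek) IPWE: consistent subjects weighted by the inverse
product of their per-stage randomization probabilities (stage-2 factor
for placebo non-responders only), which is bounded by the observed
outcome range — the raw IPWE is not a smooth estimator and the normalized
form tempers its instability.  Propensities default to empirical
frequencies (with them, the estimate provably equals direct
stratification, which is tested); known design probabilities can be
supplied.  The estimated-DTR row is fit on the full data and evaluated
against the same data, matching the construction of the original
comparison table; a sample-split would be more conservative and can be
arranged by fitting and evaluating on disjoint cohorts.  Value intervals
are percentile bootstrap on resamples shared across regimes, with the
fitted rule held fixed.

## Validation problem sizes

The acceptance suite exercises: marginal fidelity at n = 50,000 (3
Monte-Carlo SEs); exact DP equivalence on the discrete toy at n = 5,000;
coefficient recovery at n = 10,000 with unit noise (±0.1 stage 2, ±0.15
stage 1, floored at 3 analytic SEs of the realized design for the
near-collinear treatment-intercept terms, whose sampling error exceeds
the nominal band at this size); IPWE within 2 Monte-Carlo SEs of the
truth oracle at n = 20,000; exact stage-2 support recovery in ≥ 45/50
seeds at n = 4,000 with m = 5 (a priori false-inclusion probability ≈
0.07 across the ~17 one-degree null moves at the BIC penalty log n);
90% interval coverage within [0.85, 0.95] over 200 replications at
n = 500, B = 200; and post-imputation column means within 2 SEs of the
pre-masking truth at n = 2,000, m = 10.  The numbered analysis drivers
run the same pipeline at the trial's own size (n = 365), where selection
is visibly noisier — as it should be.

## Limitations

The generator draws baseline covariates independently and contains no
weekly visit structure, no informative dropout (missingness is MAR by
construction), and a single (hypo)mania indicator rather than
symptom-level criteria.  Passing tests therefore demonstrate correctness
of the estimation machinery under a faithful *design*, not fidelity to
the joint distribution of the real cohort.  Reproducing the original
subject-level coefficient tables is impossible without the trial data and
is out of scope.
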