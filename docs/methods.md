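# Methods

## Problem and estimands

Patients starting one of K medications are observed for 12 months;
treatment success is the absence of inpatient death, any hospitalization,
and any antipsychotic switch or addition over that window (treatment
discontinuation deliberately does not count as failure, since a patient
can respond well and still stop). With covariates X, arm A and success Y,
the estimands are the arm-specific success surfaces
mu_a(x) = P(Y=1 | A=a, X=x), the optimal rule d*(x) = argmax_a mu_a(x),
and the value V(d) = E[Y(d(X))] of any candidate rule d. Identification
requires no unmeasured confounding and positivity; both hold by
construction in the synthetic scenarios and neither can be guaranteed in
real claims data — the package is a methods testbed, not a clinical tool.

## Synthetic cohort generator

The generator emulates the structure of an administrative-claims study:

- **Covariates** (12 by default): age uniform on [16, 74], utilization
  counts (ED visits, prior hospitalizations, outpatient visits, Charlson
  score) as Poisson draws, and binary history indicators (sex,
  benzodiazepine, mood stabilizer, antidepressant, diabetes,
  cardiovascular disease, substance use). All linear predictors act on
  covariates standardized by their analytic moments, so ground-truth
  probabilities are exact functions of the declared parameters.
- **Assignment**: multinomial softmax of per-arm linear scores. Default
  coefficients keep per-covariate assignment odds ratios at or below 3 —
  moderate confounding that the estimators must remove. A `confounding`
  knob scales these (0 = randomized).
- **Outcome**: Bernoulli on the logit scale with shared main effects,
  per-arm intercepts, and arm-by-covariate interactions (the true effect
  heterogeneity). A `heterogeneity` knob scales both the interactions and
  the spread of the arm intercepts, so 0 yields *identical* success
  surfaces across arms — the null used for calibration checks.
- **Event streams**: every failure receives at least one
  failure-triggering event (hospitalization of either kind, switch,
  addition, or inpatient death, drawn from a fixed mix) at a uniform time
  in (0, 12]; successes receive none; discontinuation events occur
  independently of the label at rate 0.30. Event times are uniform because
  only occurrence, not timing, enters the outcome definitions (except the
  window-restricted discontinuation variant). Streams are consistent with
  the labels by construction, which is what makes the labeling round-trip
  an exact test.
- **Decoys**: an optional fraction of raw records violates exactly one
  eligibility rule each (age out of [16, 74], second-line first regimen,
  inpatient initiation), with the violated class recorded so filter tests
  are exact.

### Default scenario calibration

The default is K=5 arms, p=12 covariates, n=20 000 — a desk-scale analog
of a 15-arm, 121-predictor national-claims problem. The heterogeneity is
driven by *discrete* covariates (benzodiazepine history splits arms 1 and
2; mood-stabilizer history favors arm 3), with small age interactions on
the two dominated arms. This choice is deliberate: discrete drivers keep
per-patient decision margins bounded away from zero (under 4% of patients
have a best-vs-second-best gap below 5 points), so the oracle rule is
learnable at n=20 000, while the aggregate advantage of the oracle over
the best single arm stays realistic at about 5–6 percentage points.
Continuous-driven heterogeneity with the same aggregate gap would put a
third of patients within 3 points of the decision boundary and make rule
recovery hopeless at any desk scale. The overall success rate is ~44%.

What the generator does **not** emulate: realistic diagnosis/procedure
coding, covariate correlation structure of real claims, informative event
timing, or arm-specific censoring. Passing tests therefore demonstrate
the estimator's statistical behavior under correct identification
assumptions, not robustness to real-data pathologies.

## Cohort pipeline

Filters run in a fixed order — age in [16, 74] (inclusive), first regimen
in the allowed single-agent list (excluding clozapine, polypharmacy,
long-acting injectables), outpatient initiation, then a rare-drug minimum
(default 20 patients at n=20 000; the threshold is a parameter because
published analyses exclude "rarely prescribed" drugs without stating
one) — so exclusion counts are reproducible. Events at exactly month 0
are pre-index; the outcome window is half-open, (0, 12]. Five outcome
variants are supported (primary; psychiatric-hospitalization-or-change;
psychiatric-hospitalization-only; change-only; primary plus
discontinuation within a configurable window, default months 3–9), with
the documented nesting of their failure sets. The train/holdout split is
simple random with train size round(n × fraction), default 0.7.

## Super Learner

Out-of-fold predictions for each candidate are computed over V=10 folds
(stratified for binary targets and for the one-vs-rest propensity
indicators); the ensemble weight vector minimizes the cross-validated MSE
over the probability simplex. The optimizer evaluates the normalized
non-negative-least-squares solution, an SLSQP polish of it, and every
vertex, keeping the best — so the meta-level oracle inequality (ensemble
CV MSE no worse than the best single candidate) holds exactly, and is
asserted as an invariant. Candidates that raise on any fold get weight
zero and a warning rather than aborting. Binary targets are fit as
probability regressions under squared error and clipped to [0, 1];
second-stage difference-score targets are unbounded and never clipped.

Default roster: intercept-only mean, ridge and lasso linear models,
histogram gradient-boosted trees (depth 3, early stopping on a 15%
validation split), k-nearest-neighbors (k=50), and a cubic-spline basis
with ridge shrinkage. Early stopping in the trees and the spline ridge
penalty (alpha=10) matter: without them, flexible candidates pick up
spurious convex weight on pure-noise tasks through chance anticorrelation
of out-of-fold errors, visibly distorting fitted propensities on
randomized data. A `fast` roster (mean, ridge, shallow trees) and a
`linear` roster (mean, ridge) serve replicate-heavy simulations.

**Second-stage roster.** The per-arm difference-score models use the
roster *minus* the intercept-only candidate. On heavy-tailed AIPW targets
the CV-optimal weight on a constant predictor is substantial and differs
across arms; that shrinks each arm's fitted score by a different factor,
and the argmax of differentially shrunken scores is a worse rule even
when each regression is a better MSE predictor. Measured on the default
scenario, keeping the mean learner in stage 2 drops oracle agreement from
roughly 0.85–0.91 to 0.65–0.74. Nuisance fits keep the full roster. Pass
`cate_roster` to override.

## Two-stage ITR estimator

Propensities are one-vs-rest fits renormalized to sum to one, then
clipped below at delta = 0.01 (configurable) for denominator use only;
the renormalized probabilities are kept alongside. The clip bound guards
positivity in many-arm problems; cells below it are counted and reported.
Q_a comes from a single fit on (X, arm indicators) evaluated at each
counterfactual arm; m is fit directly on X (its identity with
sum_a g_a Q_a is kept as a diagnostic, asserted within 0.05 mean absolute
difference on synthetic data). The AIPW difference score is the default;
a plug-in variant (Q_a − m, `augmented=False`) is available. Arms with
fewer than `min_support` training patients leave the eligible set with a
warning. Ties in the argmax break toward the lowest arm index in the
configured medication order, for reproducibility.

## TMLE evaluation

Holdout nuisances are refit on the holdout sample by default (a switch
accepts transported training fits). The fluctuation is one-dimensional
on the logit scale with the clever covariate as covariate (not weight);
the score equation is solved by bracketed root-finding (Brent) to
|score| <= 1e-10, with probabilities clipped to [1e-6, 1 − 1e-6] to keep
logits finite. If nobody follows the rule the fluctuation carries no
information and epsilon stays 0. Influence values average to zero by
construction and their sample SD gives the standard error. Stochastic
allocations (uniform; observed prescription shares) are weighted
combinations of the single-arm TMLEs with linearly combined influence
values, so contrasts on the shared holdout account for correlation.
Single-arm estimates require `min_static_support` (default 30) holdout
recipients; unsupported arms are marked unavailable, mirroring published
practice of dropping rarely prescribed drugs from single-arm scenarios.
One-sided tests use the normal reference; at holdout sizes in the
thousands the t/normal distinction is immaterial. The observed-allocation
comparator is the raw empirical mean with binomial standard error, not a
TMLE of the factual rule.

Report arithmetic matches printed-precision conventions: percentages and
ratios round half-up to 1 decimal, proportional ratios to 2; NNT is
100 / (percentage-point difference), signed, so harm yields a negative
NNT; concordance ratios are defined as 0 when the numerator is 0 and
error when only the denominator is; contribution shares are
100 · d_m c_m / Σ d c and always sum to 100 (negative entries allowed).

## Permutation importance

For each arm's second-stage model, each predictor column is shuffled
(default 20 repetitions, distinct sub-seeds) and the increase in
prediction MSE against that arm's difference-score targets is averaged;
ranks break ties by predictor order. Importance is computed on the
training sample (switchable), and on a seeded subsample of at most 5 000
rows when the sample is larger — the permutation null is unaffected, only
Monte-Carlo resolution changes, and it keeps k-NN prediction costs
bounded. Correlated or duplicated predictors share credit, so a
duplicate never inflates the original's importance; irrelevant predictors
fluctuate around zero and may go slightly negative.

## Worked example on published inputs

`reference_example` packages, as plain data, the printed summary inputs
of a published 15-antipsychotic claims analysis (success rates under each
allocation scheme, per-medication prescribed shares and recommendation
counts on a 9 676-patient holdout, and the 13 (difference, count) pairs
of its gain decomposition) and recomputes every derived quantity with the
same report functions used on synthetic runs. Two printed concordance
ratios (trifluoperazine, zotepine) differ in the last decimal when
recomputed from their printed one-decimal inputs, because the original
analysis divided unrounded proportions; those two cells are not asserted.

## Problem sizes and numerical defaults

Replicate studies are sized for single-CPU runs: doubly robust
unbiasedness uses one n=100 000 cohort with oracle nuisances; TMLE
coverage uses 100 replicates of n=5 000 with correctly specified
parametric nuisances (the TMLE consumes nuisances as inputs, so this
isolates the targeting step); null calibration uses 200 replicates of
n=1 500 with the linear roster and 5 folds; rule recovery uses one
n=20 000 default-roster run. Master seeds derive per-stage seeds by fixed
offsets; identical configs reproduce identical artifacts, digest-checked
in the run manifest.

## Known limitations

- Nuisance estimation is not cross-fitted (no sample-split variant), so
  TMLE inference leans on Donsker-type conditions; with the default
  roster on smooth low-dimensional truth this is benign, as the coverage
  study shows.
- The difference score augments only the arm-specific term; the
  population surface m enters as a plug-in, which is an interpretation
  choice (E[Y|X] needs no confounding adjustment) shared by the rule's
  ranking target.
- The rule optimizes the point prediction of the difference score;
  no uncertainty-aware or constrained policy search is attempted.
- Confidence intervals for concordance ratios would require a bootstrap
  whose reproduction of published intervals is not guaranteed; none is
  asserted.
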