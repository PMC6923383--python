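# Methods

This note documents the statistical procedure the package implements,
the modelling choices made where the design was genuinely open, and
what the synthetic cohorts do and do not establish about behaviour on
real data.

## Setting and model

The target setting is a small observational cohort: n ≈ 61 trauma
patients, a binary outcome (development of multi-organ dysfunction,
MODS, prevalence 30–40%), and p ≈ 200 numeric features collected at
three post-injury time points — immune readouts (cell-surface marker
expression, stimulated responses, cytokines) plus clinical severity
scores (NISS, PS14, ISS) that repeat identically at every time point.

Candidate markers are found with penalized logistic regression.  With
log-likelihood ℓ(β₀, β) and the glmnet parameterisation, the fit solves

    min  −(1/n) ℓ(β₀, β; X, y) + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ],

intercept unpenalized, features autoscaled.  α = 1 gives the LASSO,
α = 0.5 the elastic net; both are run throughout and combined.  (Some
presentations attach the mixing weight to the opposite term; this
package fixes the convention so that α = 1 is pure L1, which is the
reading consistent with "α = 1 is the LASSO".)

## Stability selection

One selection run consists of `n_iterations` (default 100) repetitions
of:

1. a stratified 75/25 patient split (stratification keeps both outcome
   classes in every partition, which at n = 61 and 35% prevalence a
   purely random split does not guarantee; an unstratified mode
   exists);
2. λ tuning on the training portion by 10-fold stratified
   cross-validation: the grid is 100 log-spaced values from λ_max (the
   smallest λ with all-zero coefficients, computed from the KKT
   condition at the intercept-only fit) down to 10⁻³·λ_max, and the
   tuned λ minimizes pooled held-out binomial deviance (a `lambda.min`
   analogue; held-out-AUC maximization is available).  Ties break
   toward the larger, sparser λ.  λ is re-tuned inside every iteration
   rather than once up front, consistent with tuning being part of the
   subsampled procedure;
3. a refit at the tuned λ on the full training split, recording which
   coefficients are exactly nonzero and their values.

Per-feature appearance counts are then thresholded: the threshold is
the empirical quantile (numpy linear interpolation) of the full
frequency vector — zeros included — at level 0.75 by default, and
features **strictly** above it are selected.  A flat frequency vector
therefore selects nothing.  Integrated (all-time-points) analyses use
the stricter 0.90 level, since pooling three time points triples the
number of correlated candidates; the exact stricter level is a
convention exposed in `SelectionConfig`.  LASSO and elastic-net
selections are combined by union by default (per-method provenance is
retained in the result; intersection is a flag).

## Panel evaluation and the permutation null

A selected panel is evaluated by repeated random subsampling: default
1000 stratified 65/35 splits, an unpenalized binomial GLM on each
training part, Mann–Whitney ROC AUC (ties at half credit) on each test
part.  The null reference repeats the identical machinery with outcome
labels freshly permuted before every resample.  Reported summaries:
mean and SD of both samples, the empirical 2.5/97.5 percentile interval
of the real AUCs, and the permutation p-value

    p = #{ permuted AUC > mean(real AUCs) } / #permuted,

with the bias-corrected (k+1)/(B+1) variant alongside (it never returns
an exact zero).  Panels are compared to a clinical score by the
difference in mean AUC, in percentage points.

Two properties of this p-value deserve emphasis.  First, it compares
the *mean* of the real distribution against *individual* null draws;
because the mean of B resamples is much less variable than one draw,
the test is conservative under the null — in simulation the rejection
rate at the 0.05 level runs near the low edge of its binomial band
rather than at 0.05.  It is kept in this form because it is the
procedure's defined statistic.  Second, with the panel selected on the
full cohort and held fixed across resamples (the two-stage design), the
real AUCs are optimistic: selection has seen the test patients.  The
fully nested alternative — re-selecting inside every training split —
is implemented as `evaluation.nested_panel_auc` and is the honest
generalization estimate, at roughly `n_resamples ×` the cost of a
selection run; the two-stage design remains the default because it is
the structure of the procedure being reproduced.

Perfect separation of a small GLM (common with strong panels at n = 61)
is handled by a ridge-stabilized refit (L2 = 1e−4 on slopes), which
preserves the score ordering that AUC depends on; occurrences are
flagged on the fitted object.

## Preprocessing

Order: complete-case patient selection across time points → missingness
filter → minimum imputation → autoscaling (per time-point table) →
integration.  Choices:

- the 70% missingness filter is a strict inequality: a feature missing
  exactly 70% of entries is retained;
- imputation uses the per-feature observed minimum (the convention for
  assay values missing near the detection limit); no model-based
  imputation;
- autoscaling uses the n−1 denominator and records (mean, SD) for
  inversion; zero-variance features are an error rather than silently
  dropped;
- integration concatenates time-point tables and collapses clinical
  score columns that repeat with identical name and values across time
  points to a single column.  With three clinical scores shared across
  three tables of 68+68+67 features this yields the 61×197 integrated
  matrix (203 column instances − 6 duplicate copies); a same-named
  clinical column with diverging values is an error, not a silent pick;
- imputation and scaling are computed on the full table before any
  split, replicating the original procedure.  This leaks test
  information into the scaling; the leak-free variant (statistics from
  training rows only) is `preprocess.fold_standardize`, used by the
  `refit_preprocessing` switches in selection and evaluation configs.

## Synthetic cohorts

The generator emulates the study conditions: 61 patients, outcome iid
Bernoulli(0.35), three time points of 68/68/67 features of which three
are clinical scores shared across time points.  Features are
group-conditional Gaussians with equal unit variance; an informative
feature is shifted by its standardized effect size d in the event
group, so its population univariate ROC AUC is Φ(d/√2).  Defaults:

- three planted markers at d = 1.5 (AUC ≈ 0.86), one at the first and
  two at the third time point — mirroring a panel of one early
  monocyte feature and two late neutrophil features;
- clinical scores NISS d = 0.82 (AUC ≈ 0.72, the discriminative level
  reported for NISS alone), PS14 d = 1.40 (AUC ≈ 0.84), ISS d = 0.70;
- noise features in blocks of 5 with within-block correlation 0.5 via a
  shared latent factor (assay panels are correlated; the real
  correlation structure is unreported, so this is a convention);
- missingness MCAR at 5% on immune features, with two features per time
  point at 80% — deliberately above the removal threshold so the filter
  is exercised; clinical scores complete.  An outcome-dependent (MNAR)
  masking switch exists and is off by default, as the real missingness
  mechanism is uncharacterized.

Everything is reproducible from a single integer seed via per-stage
child seeds.  What passing tests on these cohorts show: the pipeline
recovers planted mean-shift signals at realistic n/p, its permutation
null is centred and (conservatively) calibrated, and its outputs are
deterministic.  What they do not show: robustness to heavy-tailed or
skewed assay distributions, informative missingness, longitudinal
within-patient kinetics (time points are independent blocks here), or
outcome-dependent censoring — conclusions about real cohorts still
require the real data.

## Numerical choices

The elastic-net path solver is an in-package coordinate descent
(IRLS outer loop, weighted least-squares inner sweeps restricted to an
active set with KKT screening, warm starts down the λ grid,
numba-compiled).  Convergence tolerance is 1e−7 on the maximum
coefficient change for reported fits and 1e−5 inside cross-validation
fold paths, where only the deviance ranking of λ values matters.  Fits
explaining >99% of the null deviance truncate the remainder of the path
(the near-separated regime at small λ; cross-validation never selects
it).  The solver is verified in the test suite against scikit-learn's
saga solver on the same objective, against the unpenalized GLM at λ = 0,
and against the closed-form soft-threshold solution on an orthogonal
Gaussian design.  The exact zero at λ ≥ λ_max is structural: no
coordinate passes the KKT screen, so no floating-point thresholding is
involved.

Degenerate situations are defined, not improvised: single-class
outcomes and non-finite inputs raise; cross-validation fold counts
shrink to the minority class size when necessary; iteration-level
failures inside stability selection are redrawn with a cap of 5× the
iteration count; an empty selected panel is reported as such and the
evaluation stage is skipped for it.

## Problem sizes in tests

The test suite exercises the method at the study's own scale (n = 61)
throughout, with iteration counts chosen per test: full 100-iteration
selection and 1000-resample evaluation in the timing/reproducibility
checks and in `scripts/acceptance.py`; 50 iterations across 50 seeded
cohorts for the marker-recovery property; 200 no-signal cohorts at
200+200 resamples for null calibration.
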