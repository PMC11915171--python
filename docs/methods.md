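# Methods

`opmdml` models the risk that an oral potentially malignant disorder
(OPMD) — here oral lichen planus (OLP) or an oral lichenoid lesion (OLL)
— undergoes malignant transformation (MT) during follow-up. The package
contains four risk models, the preprocessing pipeline they share, the
full evaluation battery used in clinical prediction research, and a
synthetic-cohort generator that stands in for the restricted hospital
data. This note records the modelling choices, their assumptions, and
what the synthetic experiments can and cannot show.

## Cohort data model

A subject is a vector of categorical clinical variables — demographics
(gender, dichotomized age at 60), risk habits (smoker-or-drinker SD vs
non-smoker-non-drinker NSND), systemic comorbidities (any, hypertension,
diabetes, hepatitis, graft-versus-host disease, previous malignancy),
lesion characteristics (OLP/OLL, white/red subtype, site, ulceration),
treatment, and oral epithelial dysplasia (OED) status at first diagnosis
and during follow-up with its grade — plus the outcome pair
`(mt_event, time_years)`. Two invariants are enforced at construction:
at least six months of follow-up (the study inclusion rule), and
consistency between OED grade and the OED flags (a grade exists iff
dysplasia was seen at baseline or follow-up). Age enters all models only
as the `>= 60` indicator; that is the dichotomy the source tables
analyze.

## Synthetic cohort generator

The real cohorts cannot be redistributed, so the generator emulates
their statistical structure:

* **Covariates** are drawn independently from the published marginal
  frequencies of the 681-patient cohort (e.g. 68.0% female, 76.2% aged
  >= 60, 61.2% buccal lesions). OED grade is drawn among
  mild/moderate/severe with weights 22:14:17 (the published grade
  counts) when an OED flag is set, and is "none" otherwise.
* **Event times** are exponential with rate `lambda0 * exp(x'beta)`
  (a constant-baseline proportional-hazards model, the simplest choice
  consistent with a Cox analysis). The nonzero `beta` are the published
  multivariate log hazard ratios: OLL 2.216, red subtype 2.391, site
  tongue 4.722 / gingiva 2.712 / others 2.006 / multiple 2.916 (vs
  buccal), OED at first diagnosis 4.210, OED during follow-up 11.850.
  All other variables carry `beta = 0`.
* **Censoring** is administrative-uniform on
  `[0.5, 20]` years. The study reports only an 8.62-year average
  follow-up, not a censoring law; uniform censoring is a stated
  stand-in, not a claim about the study.
* **Calibration.** `lambda0 = 1.1042e-3`/year was obtained once by
  root-finding on the analytic event-fraction formula so that the
  expected overall MT fraction is 0.066 over the 20-year horizon,
  matching the published 6.608% rate. `expected_event_fraction`
  enumerates the joint levels of the five active factors and integrates
  `P(T <= C)` in closed form; tests verify Monte-Carlo agreement.

**What the generator does not emulate.** Covariates are independent
(the publication gives only marginals), the baseline hazard is flat,
and effects are exactly proportional. Real clinical covariates are
strongly dependent (dysplasia co-occurs with red, tongue-site lesions),
which concentrates risk and sharpens discrimination. A direct
consequence: the generator's *analytic discrimination ceiling* — the
AUC of the true linear predictor against the 20-year MT label — is
about 0.79. No classifier can beat that in expectation on these
cohorts, so synthetic results demonstrate correctness of the pipeline
and the *ordering* of methods, not the absolute AUC levels reported on
the real data (~0.95-0.99).

A separate deterministic reconstruction (`reference_counts_cohort`)
fills per-variable columns within the MT and non-MT strata with the
exact published two-way counts, so every count-derived rate (overall
6.608%, no-dysplasia 3.185%, and so on) is recomputable exactly. The
published without-MT counts for the three dysplasia grades are
inconsistent with their row totals (17/8/6 vs the 16/7/5 implied by
total minus MT; only the latter sums to the published 636 non-MT
subjects); the reconstruction uses total minus MT.

## Preprocessing

One-hot encoding has two modes: one column per level (networks) and
reference-dropped (Cox). Standardization is fit on training data only;
zero-variance columns pass through unscaled. SMOTE is implemented
directly from its definition: each synthetic point is
`x_i + u (x_z - x_i)` with `x_z` one of the `k = 5` Euclidean nearest
minority neighbours and `u ~ U(0,1)`; originals are never modified, and
the minority class is topped up to `round(target_ratio * majority)`.
Distances are computed on the standardized one-hot matrix as-is. SMOTE
runs *inside* training folds only; balancing before the split leaks
synthetic copies of test information into training, and that variant is
available only behind an explicit `smote_before_split` flag for
replication experiments.

## The attention classifier (SANN)

Each encoded feature `x_j` becomes a token through a learned affine map
`x_j -> x_j * w_j + b_j` into `R^dv`. A single scaled dot-product
self-attention layer,

    Attention(Q, K, V) = softmax(Q K' / sqrt(dk)) V,

with learned projections `Q = E Wq`, `K = E Wk`, `V = E Wv`, re-weights
the tokens; the attended tokens are flattened and passed to a ReLU MLP
with a sigmoid output, the predicted MT probability. Disabling
attention yields the plain-MLP baseline (ANN) on the raw feature
vector. Design choices that were genuinely open and are therefore ours:
one attention head, no residual connection or layer norm (the minimal
faithful reading of the formula), binary cross-entropy loss on the MT
indicator (censoring is not modelled inside the classifier; its output
is used as a risk score for concordance), Adam optimization with
mini-batches, and early stopping on an inner validation split with the
best-epoch weights restored. Defaults: `dk = dv = 8`, hidden layers
(32, 16), dropout 0.1, learning rate 1e-3, batch size 32, at most 200
epochs, patience 20.

One numerical point matters: standardized one-hot columns for rare
levels (e.g. GVHD, 1.3% prevalence) take values near +-10, so token
embeddings initialized at unit scale saturate the softmax and stall
training. Embedding weights are initialized at scale `1/dv`, keeping
early attention logits near uniform; the projection weights use scale
`1/sqrt(dv)`.

Attention-based feature importance is the mean attention weight each
feature token *receives*, averaged over samples and query tokens and
renormalized to sum to one.

The forward/backward passes are compact hand-written numpy (verified
against finite differences in the test suite); training is bitwise
reproducible under a fixed seed on a single thread.

## Cox model, nomogram, neural Cox

`cox_fit` maximizes the Breslow-ties log partial likelihood by
Newton-Raphson with step-halving; the log partial likelihood is
monotone over iterations. Efron tie handling is available behind a
flag. Convergence is declared when the gradient sup-norm falls below
`tol` (default 1e-9) or when step-halving can no longer improve the
likelihood in double precision (at large n the gradient's attainable
floor is set by cumulative-sum round-off, ~1e-9 at n = 50,000).
Monotone likelihoods (separation) are flagged as a `ConvergenceError`
when coefficients diverge past 20 in absolute value. An optional ridge
penalty (`l2`) exists for the cross-validation harness, where rare
levels can separate inside small folds; inference uses `l2 = 0`.
Wald confidence intervals and p-values come from the inverse negative
Hessian. Variable selection follows the classical recipe: univariate
screen, then backward elimination at p >= 0.05.

The **nomogram** is an exact reparameterization of the fitted Cox
model: level points are `100 * (beta_level - min_beta_var) /
max_var_range`, so the widest-range variable spans exactly 0-100, and
total points map affinely back to the linear predictor. Survival at a
horizon is `S0(t) ** exp(lp)` with the Breslow baseline
`dH0 = d_t / sum_{risk} exp(x'beta)`; nomogram-scored probabilities
therefore equal direct Cox predictions to 1e-9 (tested). The low/high
risk split threshold defaults to 113 total points, the published
cutoff; it is configurable because the mapping from the published
95.8% survival threshold to points depends on the fitted baseline of
the original (unavailable) data.

The **neural Cox model** (DeepSurv-style) is an MLP emitting a log-risk
`g(x)`, trained full-batch on the negative Breslow partial likelihood
with Adam and the same early-stopping rule; its risk score is
`exp(g)`. With no hidden layers it is exactly a Cox model fitted by
gradient ascent, and its coefficients match `cox_fit` (tested,
correlation > 0.99).

A random-survival-forest comparator is deliberately out of scope; the
evaluation entry points accept externally produced risk-score files so
third-party forests can still be scored.

## Evaluation battery

All metrics use the convention *predicted positive iff score >=
cutoff*. The battery comprises confusion-matrix metrics (sensitivity,
specificity, accuracy, precision, NPV, F1, Youden's J — undefined
denominators surface as explicit `None`, never silently 0), ROC/AUC
(delegated to scikit-learn's Mann-Whitney implementation; tested
against an O(n^2) pair-counting oracle), the Youden-optimal cutoff
(ties resolve to the smallest cutoff), Harrell's concordance index
(comparable pairs `t_i < t_j` with the earlier subject an event; tied
risks earn half credit), the Brier score, equal-width calibration bins,
decision-curve net benefit `NB(pt) = TP/n - FP/n * pt/(1-pt)` with
treat-all and treat-none references, Kaplan-Meier curves and the
two-group log-rank test (delegated to lifelines), cumulative/dynamic
time-dependent AUC with inverse-probability-of-censoring weights from
the censoring Kaplan-Meier curve (reduces exactly to the binary AUC
when no one is censored), and Harrell's bootstrap optimism correction
for the concordance index (apparent c minus the mean of
boot-minus-original differences over B resamples).

## Experiment protocol

Cross-validation is stratified 10-fold (the source protocol says only
"randomly partitioned"; stratification keeps the ~6.6% event class in
every fold, and `stratify=False` reproduces the literal reading). Per
fold, one stratified ninth of the training folds is held out as inner
validation for early stopping; the standardizer and SMOTE see only the
remaining training data. Classification models (attention and plain
MLP) are SMOTE-balanced; the survival models (Cox, neural Cox) are not
— interpolating event times between minority neighbours has no defined
survival semantics. Metrics are reported per fold, fold-averaged (mean
and sd) and pooled over out-of-fold scores; the fold cutoff is the
Youden optimum of the fold's ROC. Hyperparameter search is an
exhaustive grid scored by inner-validation AUC with ties resolved to
grid order. External validation re-trains on the intersection of the
two cohorts' variables, fixes the classification cutoff on training
scores, and evaluates every metric on the external cohort. All
randomness derives from one experiment seed through named substreams
(fold split, inner splits, SMOTE, weight initialization).

## Problem sizes used in the shipped experiments

Parameter-recovery checks fit the five multivariate factors on a
50,000-subject synthetic cohort (the OED-grade variable is excluded
from that fit: it is deterministic given the OED flags by construction,
hence collinear). At this size the +-0.1 log-HR recovery band is about
one standard error for the rarest factor (OED at first diagnosis, 4.3%
prevalence), so individual seeds can land outside it; the shipped
experiments use the package default seed. The neural-Cox/Cox agreement
check runs at n = 20,000; cross-validated model comparisons use the
study-sized n = 681. The acceptance script runs the recovery check at
n = 20,000, a size chosen to keep the full from-scratch recomputation
interactive.

## Known limitations

* Independent covariates cap synthetic discrimination at the ~0.79
  Bayes ceiling (above); absolute synthetic AUCs are not comparable to
  the real-data values.
* The binary-outcome classifiers ignore censoring within the horizon;
  subjects censored early count as non-events, which biases their
  labels. The survival models (Cox, neural Cox, and all time-to-event
  metrics) handle censoring properly.
* The SMOTE implementation is the canonical continuous-space variant;
  no categorical-aware interpolation (SMOTE-NC) or undersampling.
* Bayesian Cox regression, time-varying covariates, stratified Cox,
  multi-head attention and SHAP-based interpretability are out of
  scope.
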