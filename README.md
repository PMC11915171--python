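# opmdml

Risk modelling for malignant transformation (MT) of oral potentially
malignant disorders (OPMDs) — oral lichen planus (OLP) and oral
lichenoid lesions (OLLs). The package is aimed at researchers building
and auditing clinical prediction models on OPMD follow-up cohorts: it
implements a self-attention neural classifier and its comparators, the
shared preprocessing pipeline, the complete survival/classification
evaluation battery, and a synthetic-cohort generator that reproduces
the statistical structure of a published 681-patient hospital cohort
whose patient-level data cannot be shared.

## What is implemented

* **Self-attention classifier (SANN).** Each encoded clinical feature
  becomes a token via a learned embedding; one scaled dot-product
  attention layer, `Attention(Q,K,V) = softmax(QK'/√d_k) V`, re-weights
  the tokens before a ReLU MLP emits the MT probability. Disabling the
  attention layer gives the plain-MLP baseline (ANN). Networks are
  compact hand-written numpy with seeded, reproducible training.
* **Cox proportional hazards** (`λ(t|x) = λ0(t) exp(x'β)`) fitted by
  Newton-Raphson on the Breslow partial likelihood, with Wald
  inference, univariate screen + backward elimination, a **nomogram**
  (exact 0–100-point reparameterization, survival `S0(t)^exp(lp)` via
  the Breslow baseline) and a 113-point low/high risk split.
* **Neural Cox (DeepSurv-style)**: an MLP log-risk trained on the
  negative Cox partial likelihood.
* **Preprocessing**: one-hot encoding, train-fold standardization, and
  a from-scratch SMOTE (synthetic minority points on segments between
  nearest minority neighbours).
* **Evaluation**: AUC, Harrell's C (with bootstrap optimism
  correction), sensitivity/specificity/accuracy/precision/NPV/F1,
  Youden's J and the Youden-optimal cutoff, Brier score, calibration
  bins, decision-curve net benefit, Kaplan-Meier + log-rank, and
  IPCW time-dependent AUC.
* **Experiment harness**: leakage-free stratified 10-fold CV
  (fold-local standardizer and SMOTE, inner validation for early
  stopping), hyperparameter grid search, and external validation on
  the shared-feature intersection of two cohorts.

## Worked example

```python
import numpy as np
from opmdml import (default_cohort_spec, generate_cohort, summarize_cohort,
                    DEFAULT_SCHEMA, one_hot_encode, cox_fit,
                    nomogram_from_cox, ExperimentConfig, run_cv)

cohort = generate_cohort(default_cohort_spec(n=681, seed=0))
print(summarize_cohort(cohort)["mt_rate_percent"])   # 7.195 (% with MT)

schema = DEFAULT_SCHEMA.subset(
    ["lesion_type", "subtype", "site", "oed_first", "oed_followup"])
X = one_hot_encode(cohort, schema, drop_reference=True)
t = np.array([r.time_years for r in cohort])
e = np.array([r.mt_event for r in cohort])
model = cox_fit(X, t, e)
print(dict(zip(model.column_names, np.round(model.hazard_ratios, 2))))
# {'lesion_type=oll': 1.34, 'subtype=red': 3.23, 'site=tongue': 5.7,
#  'site=gingiva': 3.05, 'site=others': 1.88, 'site=multiple': 3.95,
#  'oed_first=yes': 3.75, 'oed_followup=yes': 10.35}

result = run_cv(cohort, ExperimentConfig(arch="sann", seed=0))
print(round(result.mean["auc"], 3), round(result.mean["c_index"], 3))
# 0.774 0.768
```

The recovered hazard ratios scatter around the generating values
(tongue 4.72, OED during follow-up 11.85) with the sampling noise one
expects from 49 events; at n = 50,000 each log hazard ratio is
recovered within ±0.1. The cross-validated AUC is bounded by the
generator's analytic discrimination ceiling (~0.79, see
`docs/methods.md`), so on synthetic cohorts the informative comparison
is between architectures, not against real-data AUCs.

The `examples/` directory contains one narrative script per
capability (simulation, attention classifier + importances, Cox +
nomogram + risk split, four-way cross-validated comparison), and the
same workflows are scriptable via the thin CLI:

```bash
opmdml simulate --n 681 --seed 0 --out cohort.csv
opmdml cv --cohort cohort.csv --arch sann --out-dir results/
opmdml nomogram --cohort cohort.csv --out-prefix results/nomo
```

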