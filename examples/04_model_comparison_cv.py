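"""Cross-validated comparison of all four architectures.

Runs the seeded, leakage-free 10-fold protocol (fold-local
standardization and SMOTE, inner validation split for early stopping)
for the attention classifier, the plain MLP, ridge-stabilized Cox, and
the neural Cox model, and prints the fold-averaged metric battery.
"""

from opmdml import ExperimentConfig, default_cohort_spec, generate_cohort, run_cv

cohort = generate_cohort(default_cohort_spec(n=681, seed=0))

print(f"{'model':10s}{'AUC':>8s}{'sd':>7s}{'C-idx':>8s}{'sens':>7s}"
      f"{'spec':>7s}{'J':>7s}{'Brier':>8s}")
for arch in ("sann", "ann", "cox", "deepsurv"):
    res = run_cv(cohort, ExperimentConfig(arch=arch, seed=0))
    m, sd = res.mean, res.sd
    brier = f"{m['brier']:.3f}" if m["brier"] is not None else "  -"
    print(f"{arch:10s}{m['auc']:8.3f}{sd['auc']:7.3f}{m['c_index']:8.3f}"
          f"{m['sensitivity']:7.3f}{m['specificity']:7.3f}"
          f"{m['youden_j']:7.3f}{brier:>8s}")

# AUC here is capped by the generator's analytic discrimination ceiling
# (~0.79): with independent covariates and the published hazard ratios,
# even the true linear predictor cannot separate events more sharply.
# The ordering (attention model and Cox ahead of the plain MLP and the
# neural Cox) is the reproducible signal, not the absolute values.
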