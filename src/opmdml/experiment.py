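"""Experiment orchestration: stratified cross-validation with fold-local
preprocessing, hyperparameter grid search, and external validation with
feature intersection.

The leakage discipline is strict by default: the standardizer, the SMOTE
neighbourhoods, and all gradient updates see only the training folds of
each split. A ``smote_before_split`` flag reproduces the leaky variant
for replication experiments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold

from .baselines import ConvergenceError, cox_fit, deepsurv_fit
from .cohort_schema import DEFAULT_SCHEMA, FeatureSchema, PatientRecord
from .evaluation import (
    MetricReport,
    brier_score,
    classification_metrics,
    confusion_at_cutoff,
    harrell_c,
    roc_auc,
    youden_cutoff,
)
from .preprocessing import (
    DesignMatrix,
    apply_standardizer,
    fit_standardizer,
    one_hot_encode,
    smote_oversample,
)
from .sann import SannConfig, build_model, predict_risk, train_model

__all__ = [
    "ExperimentConfig",
    "CvResult",
    "stratified_kfold",
    "run_cv",
    "tune_hyperparameters",
    "external_validate",
]

logger = logging.getLogger(__name__)

_ARCHS = ("sann", "ann", "deepsurv", "cox")


@dataclass
class ExperimentConfig:
    arch: str = "sann"
    k_folds: int = 10
    seed: int = 0
    model: SannConfig = field(default_factory=SannConfig)
    smote: bool = True
    smote_k: int = 5
    smote_target_ratio: float = 1.0
    smote_before_split: bool = False
    stratify: bool = True
    output_dir: str | None = None

    def validate(self) -> None:
        if self.arch not in _ARCHS:
            raise ValueError(f"unknown arch {self.arch!r}; expected one of {_ARCHS}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        self.model.validate()


def _substream(seed: int, name: str) -> int:
    """Stable named sub-seed below 2**31."""
    h = 2166136261
    for ch in f"{seed}:{name}":
        h = ((h ^ ord(ch)) * 16777619) % (1 << 32)
    return h % (1 << 31)


def stratified_kfold(labels, k: int = 10, seed: int = 0, stratify: bool = True):
    """Fold index per record; fold sizes differ by at most one and (when
    stratified) per-fold class counts are within one of proportional."""
    labels = np.asarray(labels).astype(int)
    n = len(labels)
    if k < 2 or k > n:
        raise ValueError("k must be in [2, n]")
    if stratify:
        for cls in np.unique(labels):
            if (labels == cls).sum() < k:
                raise ValueError(
                    f"class {cls} has fewer than k={k} members; cannot stratify"
                )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n), labels)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        splits = splitter.split(np.zeros(n))
    folds = np.empty(n, dtype=int)
    for f, (_, test_idx) in enumerate(splits):
        folds[test_idx] = f
    return folds


def _encode(records, schema, arch):
    drop = arch in ("cox", "deepsurv")
    return one_hot_encode(records, schema, drop_reference=drop)


def _fit_and_score(arch, config, X_tr, y_tr, t_tr, e_tr, X_va, y_va, t_va, e_va,
                   X_te, seed):
    """Train one model on (train, val) and return scores for X_te."""
    model_cfg = replace(config.model, seed=seed)
    if arch in ("sann", "ann"):
        model = build_model(model_cfg, X_tr.shape[1], with_attention=arch == "sann")
        train_model(model, X_tr, y_tr, X_va, y_va, model_cfg)
        return predict_risk(model, X_te), model
    if arch == "deepsurv":
        model = deepsurv_fit(
            X_tr, t_tr, e_tr, model_cfg, X_val=X_va, time_val=t_va, event_val=e_va
        )
        return model.risk_score(X_te), model
    # cox: drop fold-constant columns, ridge-stabilized fit (rare levels
    # can separate in small folds), score by exp(lp)
    keep = np.flatnonzero(np.std(X_tr, axis=0) > 0)
    model = cox_fit(X_tr[:, keep], t_tr, e_tr, l2=0.1)
    return np.exp(np.clip(X_te[:, keep] @ model.beta, -500, 500)), model


def _fold_report(scores, y, t, e, probabilistic: bool) -> MetricReport:
    roc = roc_auc(scores, y)
    cut = youden_cutoff(roc)
    rep = classification_metrics(confusion_at_cutoff(scores, y, cut))
    rep.auc = roc.auc
    try:
        rep.c_index = harrell_c(scores, t, e)
    except ValueError:
        rep.c_index = None
    if probabilistic:
        rep.brier = brier_score(scores, y)
    return rep


@dataclass
class CvResult:
    per_fold: list[MetricReport]
    mean: dict[str, float | None]
    sd: dict[str, float | None]
    pooled: MetricReport
    folds: np.ndarray
    oof_scores: np.ndarray


def _aggregate(reports: list[MetricReport]):
    mean: dict = {}
    sd: dict = {}
    for key in MetricReport().as_dict():
        vals = [getattr(r, key) for r in reports if getattr(r, key) is not None]
        mean[key] = float(np.mean(vals)) if vals else None
        sd[key] = float(np.std(vals, ddof=1)) if len(vals) > 1 else None
    return mean, sd


def run_cv(
    records: Sequence[PatientRecord],
    config: ExperimentConfig,
    schema: FeatureSchema = DEFAULT_SCHEMA,
) -> CvResult:
    """Stratified k-fold cross-validation of one architecture.

    Per fold: fit standardizer on the training folds, hold out one
    stratified ninth of them as inner validation for early stopping,
    SMOTE-balance the remaining training data (classification models
    only), train, and score the held-out fold. Reports per-fold,
    fold-averaged (mean and sd), and pooled out-of-fold metrics.
    """
    config.validate()
    records = list(records)
    y = np.array([int(r.mt_event) for r in records])
    t = np.array([r.time_years for r in records])
    e = y.astype(bool)
    X_all = _encode(records, schema, config.arch)
    probabilistic = config.arch in ("sann", "ann")

    folds = stratified_kfold(
        y, config.k_folds, _substream(config.seed, "folds"), config.stratify
    )

    leaky = None
    if config.smote_before_split and probabilistic and config.smote:
        # replication variant: balance once on the full standardized data
        s_all = fit_standardizer(X_all)
        Z_all = apply_standardizer(s_all, X_all)
        leaky = smote_oversample(
            Z_all, y, k=config.smote_k, target_ratio=config.smote_target_ratio,
            seed=_substream(config.seed, "smote_global"),
        )

    reports: list[MetricReport] = []
    oof = np.full(len(records), np.nan)
    for f in range(config.k_folds):
        test = folds == f
        train = ~test
        tr_idx = np.flatnonzero(train)
        # inner validation: one stratified share of the training folds
        inner = stratified_kfold(
            y[tr_idx], max(config.k_folds - 1, 2),
            _substream(config.seed, f"inner{f}"), config.stratify,
        )
        va_idx = tr_idx[inner == 0]
        st_idx = tr_idx[inner != 0]

        Xtr = DesignMatrix(X_all.values[st_idx], X_all.column_names,
                           [X_all.row_ids[i] for i in st_idx])
        std = fit_standardizer(Xtr)
        Ztr = apply_standardizer(std, Xtr).values
        Zva = (X_all.values[va_idx] - std.mean) / std.sd
        Zte = (X_all.values[test] - std.mean) / std.sd
        ytr = y[st_idx]

        if probabilistic and config.smote and not config.smote_before_split:
            Xs, ys = smote_oversample(
                DesignMatrix(Ztr, X_all.column_names,
                             [X_all.row_ids[i] for i in st_idx]),
                ytr, k=config.smote_k, target_ratio=config.smote_target_ratio,
                seed=_substream(config.seed, f"smote{f}"),
            )
            Ztr, ytr = Xs.values, ys
            ttr = np.concatenate([t[st_idx], np.full(len(ys) - len(st_idx), np.nan)])
            etr = ys.astype(bool)
        elif leaky is not None:
            Zl, yl = leaky
            mask = np.ones(Zl.shape[0], dtype=bool)
            mask[np.flatnonzero(test)] = False  # synthetic rows always kept
            Ztr, ytr = Zl.values[mask], yl[mask]
            ttr, etr = t[st_idx], e[st_idx]
            Zva = apply_standardizer(fit_standardizer(X_all), X_all).values[va_idx]
            Zte = apply_standardizer(fit_standardizer(X_all), X_all).values[test]
        else:
            ttr, etr = t[st_idx], e[st_idx]

        scores, _ = _fit_and_score(
            config.arch, config, Ztr, ytr, ttr, etr,
            Zva, y[va_idx], t[va_idx], e[va_idx], Zte,
            _substream(config.seed, f"init{f}"),
        )
        oof[test] = scores
        rep = _fold_report(scores, y[test], t[test], e[test], probabilistic)
        reports.append(rep)
        logger.info("fold %d: auc=%.4f", f, rep.auc)

    mean, sd = _aggregate(reports)
    pooled = _fold_report(oof, y, t, e, probabilistic)
    result = CvResult(reports, mean, sd, pooled, folds, oof)
    if config.output_dir:
        _write_outputs(result, config)
    return result


def _write_outputs(result: CvResult, config: ExperimentConfig) -> None:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "arch": config.arch,
        "mean": result.mean,
        "sd": result.sd,
        "pooled": result.pooled.as_dict(),
        "per_fold": [r.as_dict() for r in result.per_fold],
    }
    (out / "metrics.json").write_text(json.dumps(payload, indent=2))
    lines = ["fold," + ",".join(MetricReport().as_dict())]
    for f, r in enumerate(result.per_fold):
        vals = [("" if v is None else f"{v:.6f}") for v in r.as_dict().values()]
        lines.append(f"{f}," + ",".join(vals))
    (out / "folds.csv").write_text("\n".join(lines) + "\n")


def tune_hyperparameters(
    records: Sequence[PatientRecord],
    grid: Sequence[SannConfig],
    config: ExperimentConfig,
    schema: FeatureSchema = DEFAULT_SCHEMA,
):
    """Exhaustive grid search scored by inner-validation AUC.

    The cohort is split once (stratified, seeded) into a training part and
    an inner validation part; each candidate is trained on the former and
    scored on the latter. Ties resolve to the earliest grid entry.
    Returns ``(best_config, leaderboard)`` where the leaderboard is a list
    of ``(grid_index, auc)`` in grid order.
    """
    config.validate()
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    records = list(records)
    y = np.array([int(r.mt_event) for r in records])
    t = np.array([r.time_years for r in records])
    folds = stratified_kfold(
        y, config.k_folds, _substream(config.seed, "tune"), config.stratify
    )
    va = folds == 0
    tr = ~va
    X_all = _encode(records, schema, config.arch)
    Xtr = DesignMatrix(X_all.values[tr], X_all.column_names,
                       [X_all.row_ids[i] for i in np.flatnonzero(tr)])
    std = fit_standardizer(Xtr)
    Ztr = apply_standardizer(std, Xtr).values
    Zva = (X_all.values[va] - std.mean) / std.sd
    ytr = y[tr]
    if config.smote and config.arch in ("sann", "ann"):
        Xs, ys = smote_oversample(
            DesignMatrix(Ztr, X_all.column_names, Xtr.row_ids), ytr,
            k=config.smote_k, target_ratio=config.smote_target_ratio,
            seed=_substream(config.seed, "tune_smote"),
        )
        Ztr, ytr = Xs.values, ys

    leaderboard = []
    best_auc, best_cfg = -np.inf, None
    for i, cand in enumerate(grid):
        cand.validate()
        scores, _ = _fit_and_score(
            config.arch, replace(config, model=cand),
            Ztr, ytr, t[tr], y[tr].astype(bool),
            Zva, y[va], t[va], y[va].astype(bool), Zva,
            _substream(config.seed, f"tune{i}"),
        )
        auc = roc_auc(scores, y[va]).auc
        leaderboard.append((i, float(auc)))
        if auc > best_auc + 1e-12:
            best_auc, best_cfg = auc, cand
    return best_cfg, leaderboard


def external_validate(
    config: ExperimentConfig,
    train_records: Sequence[PatientRecord],
    external_records: Sequence[PatientRecord],
    train_schema: FeatureSchema = DEFAULT_SCHEMA,
    external_schema: FeatureSchema = DEFAULT_SCHEMA,
) -> MetricReport:
    """Re-train on the shared feature set, evaluate on the external cohort.

    The feature set is the intersection of the two schemas' variables; the
    model is re-trained on ``train_records`` restricted to it (with an
    inner validation split for early stopping), the classification cutoff
    is fixed on the training scores, and all metrics are computed on the
    external cohort.
    """
    config.validate()
    shared = [v for v in train_schema.variables if v in set(external_schema.variables)]
    if not shared:
        raise ValueError("no shared features between cohorts")
    schema = train_schema.subset(shared)

    train_records = list(train_records)
    y = np.array([int(r.mt_event) for r in train_records])
    t = np.array([r.time_years for r in train_records])
    X_all = _encode(train_records, schema, config.arch)
    inner = stratified_kfold(
        y, max(config.k_folds - 1, 2), _substream(config.seed, "ext"), config.stratify
    )
    va = inner == 0
    tr = ~va
    Xtr = DesignMatrix(X_all.values[tr], X_all.column_names,
                       [X_all.row_ids[i] for i in np.flatnonzero(tr)])
    std = fit_standardizer(Xtr)
    Ztr = apply_standardizer(std, Xtr).values
    Zva = (X_all.values[va] - std.mean) / std.sd
    ytr = y[tr]
    if config.smote and config.arch in ("sann", "ann"):
        Xs, ys = smote_oversample(
            DesignMatrix(Ztr, X_all.column_names, Xtr.row_ids), ytr,
            k=config.smote_k, target_ratio=config.smote_target_ratio,
            seed=_substream(config.seed, "ext_smote"),
        )
        Ztr, ytr = Xs.values, ys

    X_ext = _encode(list(external_records), schema, config.arch)
    Z_ext = (X_ext.values - std.mean) / std.sd
    Z_train_full = (X_all.values - std.mean) / std.sd

    scores_ext, model = _fit_and_score(
        config.arch, config, Ztr, ytr, t[tr], y[tr].astype(bool),
        Zva, y[va], t[va], y[va].astype(bool), Z_ext,
        _substream(config.seed, "ext_init"),
    )
    if config.arch in ("sann", "ann"):
        scores_train = predict_risk(model, Z_train_full)
    elif config.arch == "deepsurv":
        scores_train = model.risk_score(Z_train_full)
    else:
        keep = np.flatnonzero(np.std(Ztr, axis=0) > 0)
        scores_train = np.exp(np.clip(Z_train_full[:, keep] @ model.beta, -500, 500))

    y_ext = np.array([int(r.mt_event) for r in external_records])
    t_ext = np.array([r.time_years for r in external_records])
    cut = youden_cutoff(roc_auc(scores_train, y))
    rep = classification_metrics(confusion_at_cutoff(scores_ext, y_ext, cut))
    rep.auc = roc_auc(scores_ext, y_ext).auc
    try:
        rep.c_index = harrell_c(scores_ext, t_ext, y_ext.astype(bool))
    except ValueError:
        rep.c_index = None
    if config.arch in ("sann", "ann"):
        rep.brier = brier_score(scores_ext, y_ext)
    return rep
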