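"""Comparator survival models: Cox proportional hazards with nomogram
scoring, and a neural Cox (DeepSurv-style) risk model.

The Cox fitter maximizes the Breslow-ties log partial likelihood by
Newton-Raphson with step-halving (Efron ties available behind a flag);
the nomogram is an exact reparameterization of the fitted model onto the
conventional 0-100 point scale, so nomogram survival probabilities equal
direct Cox predictions ``S0(t)**exp(lp)``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._nn import MLP, Adam
from .cohort_schema import DEFAULT_SCHEMA, FeatureSchema, PatientRecord
from .preprocessing import DesignMatrix, one_hot_encode

__all__ = [
    "CoxModel",
    "BaselineSurvival",
    "ConvergenceError",
    "cox_fit",
    "breslow_baseline",
    "Nomogram",
    "nomogram_from_cox",
    "risk_group_split",
    "NeuralCoxModel",
    "deepsurv_fit",
    "univariate_cox",
    "backward_eliminate",
]


class ConvergenceError(RuntimeError):
    """Raised when the partial-likelihood maximization does not converge
    (e.g. monotone likelihood under separation)."""


@dataclass
class BaselineSurvival:
    """Breslow baseline survival: a right-continuous step function
    ``S0(t) = exp(-H0(t))`` with jumps at event times."""

    times: np.ndarray
    cumhaz: np.ndarray

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if len(self.times) == 0:  # no events: survival is identically 1
            return np.ones_like(t)
        idx = np.searchsorted(self.times, t, side="right") - 1
        H = np.where(idx >= 0, self.cumhaz[np.maximum(idx, 0)], 0.0)
        return np.exp(-H)


@dataclass
class CoxModel:
    """Fitted proportional-hazards model on a reference-dropped encoding."""

    column_names: list[str]
    beta: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    n_iter: int
    baseline: BaselineSurvival | None = None
    ties: str = "breslow"

    @property
    def hazard_ratios(self) -> np.ndarray:
        return np.exp(self.beta)

    def confidence_intervals(self, alpha: float = 0.05):
        """Wald (1-alpha) CIs for the hazard ratios."""
        se = np.sqrt(np.diag(self.cov))
        z = stats.norm.ppf(1 - alpha / 2)
        return np.exp(self.beta - z * se), np.exp(self.beta + z * se)

    def p_values(self) -> np.ndarray:
        se = np.sqrt(np.diag(self.cov))
        z = self.beta / se
        return 2 * stats.norm.sf(np.abs(z))

    def linear_predictor(self, X) -> np.ndarray:
        V = X.values if isinstance(X, DesignMatrix) else np.asarray(X, float)
        return V @ self.beta

    def predict_survival(self, X, t) -> np.ndarray:
        """``S(t|x) = S0(t) ** exp(x'beta)`` (requires a fitted baseline)."""
        if self.baseline is None:
            raise ValueError("no baseline survival attached; call breslow_baseline")
        lp = self.linear_predictor(X)
        return self.baseline(t) ** np.exp(lp)


def _as_xy(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, DesignMatrix):
        return X.values, list(X.column_names)
    V = np.asarray(X, dtype=float)
    return V, [f"x{j}" for j in range(V.shape[1])]


def _group_starts(ts: np.ndarray):
    """Start index of each distinct-time group and per-subject group id
    for an ascending-sorted time vector."""
    new = np.r_[True, ts[1:] != ts[:-1]]
    return np.flatnonzero(new), np.cumsum(new) - 1


def _neg_partial_lik_terms(beta, V, time, event, ties):
    """Log partial likelihood, gradient and Hessian (Breslow or Efron)."""
    n, d = V.shape
    order = np.argsort(time, kind="stable")
    Vs, ts, es = V[order], time[order], event[order]
    eta = Vs @ beta
    eta = np.clip(eta, -500, 500)
    w = np.exp(eta)
    wX = w[:, None] * Vs
    wXX = np.einsum("i,ij,ik->ijk", w, Vs, Vs)
    # suffix (risk-set) sums: risk set of time t = all with time >= t
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum(wX[::-1], axis=0)[::-1]
    S2 = np.cumsum(wXX[::-1], axis=0)[::-1]

    starts, gid = _group_starts(ts)
    m_g = np.bincount(gid[es], minlength=len(starts))
    ev = np.flatnonzero(m_g > 0)

    xsum = Vs[es].sum(axis=0)
    ll = float(eta[es].sum())
    grad = xsum.copy()
    hess = np.zeros((d, d))

    if ties == "breslow":
        idx = starts[ev]
        mg = m_g[ev].astype(float)
        s0, s1, s2 = S0[idx], S1[idx], S2[idx]
        ll -= float((mg * np.log(s0)).sum())
        r1 = s1 / s0[:, None]
        grad -= (mg[:, None] * r1).sum(axis=0)
        hess -= (
            mg[:, None, None]
            * (s2 / s0[:, None, None] - np.einsum("gi,gj->gij", r1, r1))
        ).sum(axis=0)
    else:  # efron: loop over event groups only (used on modest n)
        for g in ev:
            i = starts[g]
            j = starts[g + 1] if g + 1 < len(starts) else n
            dead = np.flatnonzero(es[i:j]) + i
            m = len(dead)
            wd = w[dead].sum()
            wd1 = wX[dead].sum(axis=0)
            wd2 = wXX[dead].sum(axis=0)
            for l in range(m):
                f = l / m
                s0 = S0[i] - f * wd
                s1 = S1[i] - f * wd1
                s2 = S2[i] - f * wd2
                ll -= np.log(s0)
                r1 = s1 / s0
                grad -= r1
                hess -= s2 / s0 - np.outer(r1, r1)
    return ll, grad, hess


def cox_fit(
    X,
    time,
    event,
    tol: float = 1e-9,
    max_iter: int = 100,
    ties: str = "breslow",
    l2: float = 0.0,
) -> CoxModel:
    """Newton-Raphson maximization of the Cox log partial likelihood.

    Iterates with step-halving (the log partial likelihood never
    decreases) until the gradient sup-norm falls below ``tol``. Raises
    :class:`ConvergenceError` when the likelihood is monotone
    (separation) and ``ValueError`` for constant columns or event-free
    data. ``l2 > 0`` adds a ridge penalty ``-l2/2 * ||beta||^2`` (used by
    the cross-validation harness to stabilize small folds with rare
    levels; leave 0 for inference).
    """
    V, names = _as_xy(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if ties not in ("breslow", "efron"):
        raise ValueError("ties must be 'breslow' or 'efron'")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    if V.shape[0] != len(time) or len(time) != len(event):
        raise ValueError("X, time, event length mismatch")
    if np.any(V.std(axis=0) == 0):
        bad = [names[j] for j in np.flatnonzero(V.std(axis=0) == 0)]
        raise ValueError(f"constant column(s): {', '.join(bad)}")

    def _terms(b):
        ll, grad, hess = _neg_partial_lik_terms(b, V, time, event, ties)
        if l2 > 0:
            ll -= 0.5 * l2 * float(b @ b)
            grad = grad - l2 * b
            hess = hess - l2 * np.eye(len(b))
        return ll, grad, hess

    beta = np.zeros(V.shape[1])
    ll, grad, hess = _terms(beta)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        if np.max(np.abs(grad)) < tol:
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"singular Hessian at iteration {n_iter}") from exc
        scale = 1.0
        stalled = True
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = _terms(cand)
            if ll_new > ll + 1e-12:
                stalled = False
                break
            scale *= 0.5
        if stalled:
            # the ascent direction cannot improve the likelihood within
            # double precision: we are at the optimum representable in
            # floating point even if the gradient sits above tol
            break
        beta, ll, grad, hess = cand, ll_new, g_new, h_new
    if np.max(np.abs(beta)) > 20:
        raise ConvergenceError(
            "coefficients diverging; monotone likelihood (separation) suspected"
        )
    else:
        if np.max(np.abs(grad)) >= max(tol, 1e-4):
            raise ConvergenceError(
                f"no convergence in {max_iter} iterations (|grad|={np.max(np.abs(grad)):.2e})"
            )
    cov = np.linalg.inv(-hess)
    model = CoxModel(names, beta, cov, float(ll), n_iter, ties=ties)
    model.baseline = breslow_baseline(model, V, time, event)
    return model


def breslow_baseline(model: CoxModel, X, time, event) -> BaselineSurvival:
    """Breslow estimator: ``dH0(t) = d_t / sum_{risk set} exp(x'beta)``."""
    V, _ = _as_xy(X)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    order = np.argsort(time, kind="stable")
    Vs, ts, es = V[order], time[order], event[order]
    w = np.exp(np.clip(Vs @ model.beta, -500, 500))
    S0 = np.cumsum(w[::-1])[::-1]
    times, increments = [], []
    i, n = 0, len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        m = int(es[i:j].sum())
        if m > 0:
            times.append(ts[i])
            increments.append(m / S0[i])
        i = j
    return BaselineSurvival(np.asarray(times), np.cumsum(increments))


# ---------------------------------------------------------------------------
# Nomogram


@dataclass
class Nomogram:
    """0-100 point reparameterization of a fitted Cox model.

    ``points[var][level]`` maps each clinical level to its points; the
    variable with the widest coefficient range spans exactly 0-100. Total
    points convert back to the Cox linear predictor as
    ``lp = total * beta_per_point + offset``, making survival predictions
    an exact restatement of the Cox model.
    """

    points: dict[str, dict[str, float]]
    beta_per_point: float
    offset: float
    baseline: BaselineSurvival
    horizons: tuple[float, ...] = (3.0, 5.0, 10.0, 20.0)

    def score_record(self, record: PatientRecord) -> float:
        return sum(
            table[record.level(v)] for v, table in self.points.items()
        )

    def score_cohort(self, records) -> np.ndarray:
        return np.array([self.score_record(r) for r in records])

    def linear_predictor(self, total_points) -> np.ndarray:
        return np.asarray(total_points, float) * self.beta_per_point + self.offset

    def survival_at(self, total_points, t) -> np.ndarray:
        """Event-free probability at time ``t`` for a total score."""
        lp = self.linear_predictor(total_points)
        return self.baseline(t) ** np.exp(lp)

    def point_table(self) -> dict:
        """JSON-friendly summary including survival at the horizons for a
        grid of total points."""
        lo = sum(min(tb.values()) for tb in self.points.values())
        hi = sum(max(tb.values()) for tb in self.points.values())
        grid = np.linspace(lo, hi, 21)
        return {
            "points": self.points,
            "total_points_grid": grid.tolist(),
            "event_free": {
                str(h): self.survival_at(grid, h).tolist() for h in self.horizons
            },
        }


def nomogram_from_cox(
    model: CoxModel,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    horizons: tuple[float, ...] = (3.0, 5.0, 10.0, 20.0),
) -> Nomogram:
    """Build the point mapping from a Cox fit on ``var=level`` columns.

    Points for a level are ``100 * (beta_level - min_beta_var) /
    max_var_range``; the reference level carries coefficient 0.
    """
    if model.baseline is None:
        raise ValueError("model needs a baseline survival")
    contrib: dict[str, dict[str, float]] = {}
    for name, b in zip(model.column_names, model.beta):
        if "=" not in name:
            raise ValueError(f"column {name!r} not in 'variable=level' form")
        v, lv = name.split("=", 1)
        contrib.setdefault(v, {})[lv] = float(b)
    for v in contrib:
        if v not in schema.variables:
            raise ValueError(f"unknown variable {v!r}")
        for lv in schema.levels[v]:
            contrib[v].setdefault(lv, 0.0)
    ranges = {v: max(tb.values()) - min(tb.values()) for v, tb in contrib.items()}
    max_range = max(ranges.values())
    if max_range <= 0:
        raise ValueError("all coefficients are zero; nomogram undefined")
    points = {
        v: {lv: 100.0 * (b - min(tb.values())) / max_range for lv, b in tb.items()}
        for v, tb in contrib.items()
    }
    offset = sum(min(tb.values()) for tb in contrib.values())
    return Nomogram(
        points=points,
        beta_per_point=max_range / 100.0,
        offset=offset,
        baseline=model.baseline,
        horizons=tuple(horizons),
    )


def risk_group_split(
    nomogram: Nomogram, records, cutoff_points: float = 113.0
) -> dict[str, list[PatientRecord]]:
    """Split a cohort into low/high risk at a total-points cutoff.

    A record is high risk iff its total points exceed ``cutoff_points``
    (default 113, the published low/high boundary).
    """
    groups: dict[str, list[PatientRecord]] = {"low": [], "high": []}
    for r in records:
        total = nomogram.score_record(r)
        groups["high" if total > cutoff_points else "low"].append(r)
    return groups


# ---------------------------------------------------------------------------
# Neural Cox (DeepSurv-style)


class NeuralCoxModel:
    """MLP emitting a log-risk ``g(x)``; risk score is ``exp(g(x))``."""

    def __init__(self, config, n_features: int):
        config.validate()
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.n_features = n_features
        self.mlp = MLP([n_features, *config.hidden_sizes, 1], rng)
        self.history: dict = {"train_loss": []}

    def log_risk(self, X) -> np.ndarray:
        z, _ = self.mlp.forward(np.asarray(X, float))
        return z[:, 0]

    def risk_score(self, X) -> np.ndarray:
        return np.exp(np.clip(self.log_risk(X), -500, 500))

    @property
    def coefficients(self) -> np.ndarray:
        """Input-layer weights; for the zero-hidden-layer (linear)
        variant these play the role of Cox coefficients."""
        if len(self.mlp.W) != 1:
            raise ValueError("coefficients defined only for the linear variant")
        return self.mlp.W[0][:, 0]


def _neg_breslow_loss_and_grad(g, time, event):
    """Full-batch negative Breslow partial likelihood of log-risks ``g``
    and its gradient d loss / d g (normalized by the number of events)."""
    n = len(g)
    order = np.argsort(time, kind="stable")
    gs, ts, es = g[order], time[order], np.asarray(event, bool)[order]
    w = np.exp(np.clip(gs, -500, 500))
    S0 = np.cumsum(w[::-1])[::-1]
    n_ev = int(es.sum())
    starts, gid = _group_starts(ts)
    m_g = np.bincount(gid[es], minlength=len(starts)).astype(float)
    s0_g = S0[starts]
    ll = float(gs[es].sum() - (m_g * np.log(np.where(m_g > 0, s0_g, 1.0))).sum())
    # cumulative d_g / S0 up to and including each subject's time
    cum_ratio = np.cumsum(m_g / s0_g)[gid]
    dg_sorted = -es.astype(float) + w * cum_ratio
    dg = np.empty(n)
    dg[order] = dg_sorted / n_ev
    return -ll / n_ev, dg


def deepsurv_fit(
    X,
    time,
    event,
    config,
    X_val=None,
    time_val=None,
    event_val=None,
) -> NeuralCoxModel:
    """Fit the neural Cox model by full-batch Adam on the negative
    Breslow partial likelihood, with early stopping on the validation
    loss (training loss when no validation set is supplied)."""
    V, _ = _as_xy(X)
    time = np.asarray(time, float)
    event = np.asarray(event).astype(bool)
    if event.sum() < 1:
        raise ValueError("need at least one event")
    model = NeuralCoxModel(config, V.shape[1])
    opt = Adam(model.mlp.parameters(), lr=config.learning_rate)
    has_val = X_val is not None
    if has_val:
        Vv, _ = _as_xy(X_val)
        tv = np.asarray(time_val, float)
        ev = np.asarray(event_val).astype(bool)
        if ev.sum() < 1:
            raise ValueError("validation set has no events")
    best = np.inf
    best_params = None
    stall = 0
    for _ in range(config.max_epochs):
        z, caches = model.mlp.forward(V)
        loss, dg = _neg_breslow_loss_and_grad(z[:, 0], time, event)
        _, grads = model.mlp.backward(caches, dg[:, None])
        params = model.mlp.parameters()
        opt.step(params, grads)
        model.mlp.set_parameters(params)
        model.history["train_loss"].append(loss)
        if has_val:
            monitor, _ = _neg_breslow_loss_and_grad(model.log_risk(Vv), tv, ev)
        else:
            monitor = loss
        if monitor < best - 1e-12:
            best = monitor
            best_params = [p.copy() for p in model.mlp.parameters()]
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    if best_params is not None:
        model.mlp.set_parameters(best_params)
    return model


# ---------------------------------------------------------------------------
# Variable selection (univariate screen + backward elimination)


def univariate_cox(records, time, event, schema: FeatureSchema = DEFAULT_SCHEMA):
    """Per-variable Cox fits; returns {variable: {level: (HR, lo, hi, p)}}."""
    out: dict[str, dict[str, tuple]] = {}
    for v in schema.variables:
        sub = schema.subset([v])
        X = one_hot_encode(records, sub, drop_reference=True)
        try:
            m = cox_fit(X, time, event)
        except (ValueError, ConvergenceError):
            continue
        lo, hi = m.confidence_intervals()
        ps = m.p_values()
        out[v] = {
            name.split("=", 1)[1]: (float(np.exp(b)), float(l), float(h), float(p))
            for name, b, l, h, p in zip(m.column_names, m.beta, lo, hi, ps)
        }
    return out


def backward_eliminate(
    records,
    time,
    event,
    variables,
    schema: FeatureSchema = DEFAULT_SCHEMA,
    threshold: float = 0.05,
):
    """Backward stepwise elimination at the variable level.

    Repeatedly drops the variable whose strongest level has the largest
    Wald p-value above ``threshold`` until all remaining variables carry
    at least one level with p < threshold. Returns (kept variables,
    final CoxModel).
    """
    kept = list(variables)
    while True:
        sub = schema.subset(kept)
        X = one_hot_encode(records, sub, drop_reference=True)
        model = cox_fit(X, time, event)
        ps = model.p_values()
        best_p: dict[str, float] = {}
        for name, p in zip(model.column_names, ps):
            v = name.split("=", 1)[0]
            best_p[v] = min(best_p.get(v, 1.0), float(p))
        worst = max(kept, key=lambda v: best_p[v])
        if best_p[worst] <= threshold or len(kept) == 1:
            return kept, model
        kept.remove(worst)
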