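"""Metric battery: confusion metrics, ROC, concordance, calibration,
decision curves, Kaplan-Meier/log-rank, time-dependent AUC, bootstrap."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from opmdml.evaluation import (
    ConfusionCounts,
    bootstrap_cindex,
    brier_score,
    calibration_bins,
    classification_metrics,
    confusion_at_cutoff,
    decision_curve,
    harrell_c,
    km_curve,
    logrank,
    roc_auc,
    time_dependent_auc,
    youden_cutoff,
)


def pair_auc(scores, labels):
    """O(n^2) pair-counting oracle for the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def pair_cindex(risk, time, event):
    """Exhaustive comparable-pair oracle for Harrell's c."""
    num = den = 0.0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                den += 1
                if risk[i] > risk[j]:
                    num += 1
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den


class TestConfusionAndMetrics:
    def test_cutoff_extremes(self):
        scores = np.array([0.2, 0.5, 0.9])
        labels = np.array([0, 1, 1])
        all_pos = confusion_at_cutoff(scores, labels, 0.0)
        assert (all_pos.tp, all_pos.fp, all_pos.tn, all_pos.fn) == (2, 1, 0, 0)
        all_neg = confusion_at_cutoff(scores, labels, 1.1)
        assert (all_neg.tn, all_neg.fn) == (1, 2)

    def test_six_point_enumeration(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8, 0.65, 0.05])
        labels = np.array([0, 0, 1, 1, 1, 0])
        c = confusion_at_cutoff(scores, labels, 0.4)
        # manual: predicted positive = {0.4, 0.8, 0.65}
        assert (c.tp, c.fp, c.tn, c.fn) == (2, 1, 2, 1)

    def test_direct_fraction_example(self):
        rep = classification_metrics(ConfusionCounts(tp=3, fp=1, tn=4, fn=2))
        assert rep.sensitivity == pytest.approx(0.6)
        assert rep.specificity == pytest.approx(0.8)
        assert rep.accuracy == pytest.approx(0.7)
        assert rep.precision == pytest.approx(0.75)
        assert rep.npv == pytest.approx(2 / 3)
        assert rep.f1 == pytest.approx(2 / 3)
        assert rep.youden_j == pytest.approx(0.4)

    def test_perfect_classifier_all_ones(self):
        rep = classification_metrics(ConfusionCounts(tp=5, fp=0, tn=5, fn=0))
        for field in ("sensitivity", "specificity", "accuracy", "precision",
                      "npv", "f1", "youden_j"):
            assert getattr(rep, field) == pytest.approx(1.0 if field != "youden_j" else 1.0)

    def test_zero_denominators_become_none(self):
        rep = classification_metrics(ConfusionCounts(tp=0, fp=0, tn=3, fn=2))
        assert rep.precision is None
        assert rep.sensitivity == 0.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(tp=st.integers(0, 20), fp=st.integers(0, 20),
           tn=st.integers(0, 20), fn=st.integers(0, 20))
    def test_youden_identity_holds(self, tp, fp, tn, fn):
        rep = classification_metrics(ConfusionCounts(tp, fp, tn, fn))
        if rep.sensitivity is not None and rep.specificity is not None:
            assert rep.youden_j == pytest.approx(
                rep.sensitivity + rep.specificity - 1, abs=1e-12)
        if rep.f1 is not None:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.sensitivity
                / (rep.precision + rep.sensitivity), abs=1e-12)


class TestRoc:
    def test_separated_scores_auc_one(self):
        roc = roc_auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0]))
        assert roc.auc == 1.0

    def test_constant_scores_auc_half(self):
        roc = roc_auc(np.full(10, 0.5), np.r_[np.ones(5), np.zeros(5)].astype(int))
        assert roc.auc == 0.5

    def test_matches_pair_oracle(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[0], labels[1] = 0, 1
        assert roc_auc(scores, labels).auc == pytest.approx(
            pair_auc(scores, labels), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_youden_cutoff_matches_brute_force(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        roc = youden_cutoff(roc_auc(scores, labels))
        best_j, best_cut = -np.inf, None
        for cut in sorted(np.unique(scores)):
            c = confusion_at_cutoff(scores, labels, cut)
            rep = classification_metrics(c)
            j = rep.youden_j
            if j > best_j + 1e-12:
                best_j, best_cut = j, cut
        assert roc == pytest.approx(best_cut)

    def test_separable_cutoff_is_smallest_positive_score(self):
        scores = np.array([0.9, 0.7, 0.3, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert youden_cutoff(roc_auc(scores, labels)) == pytest.approx(0.7)


class TestHarrellC:
    def test_perfect_and_reversed(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        event = np.ones(4, bool)
        assert harrell_c(np.array([4.0, 3, 2, 1]), time, event) == 1.0
        assert harrell_c(np.array([1.0, 2, 3, 4]), time, event) == 0.0

    def test_censored_toy_matches_pair_enumeration(self):
        risk = np.array([0.9, 0.3, 0.8, 0.2, 0.5])
        time = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        event = np.array([1, 0, 1, 0, 1], dtype=bool)
        assert harrell_c(risk, time, event) == pytest.approx(
            pair_cindex(risk, time, event))

    def test_matches_lifelines(self, rng):
        from lifelines.utils import concordance_index

        risk = rng.normal(size=60)
        time = rng.exponential(5, 60)
        event = rng.uniform(size=60) < 0.6
        event[0] = True
        ours = harrell_c(risk, time, event)
        theirs = concordance_index(time, -risk, event.astype(int))
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            harrell_c(np.array([1.0, 2.0]), np.array([1.0, 2.0]),
                      np.zeros(2, bool))


class TestBrierAndCalibration:
    def test_brier_limits(self):
        y = np.array([1, 0, 1])
        assert brier_score(np.array([1.0, 0.0, 1.0]), y) == 0.0
        assert brier_score(np.full(3, 0.5), y) == 0.25

    def test_brier_toy_arithmetic(self):
        assert brier_score(np.array([0.8, 0.4]), np.array([1, 0])) == pytest.approx(
            ((0.8 - 1) ** 2 + 0.4**2) / 2)

    def test_calibrated_draws_recovered(self, rng):
        p = rng.uniform(size=100_000)
        y = (rng.uniform(size=p.size) < p).astype(int)
        bins = calibration_bins(p, y, n_bins=10)
        assert len(bins) == 10
        for mean_pred, obs, count in bins:
            assert abs(obs - mean_pred) < 0.01

    def test_constant_probability_single_bin(self):
        bins = calibration_bins(np.full(20, 0.42), np.r_[np.ones(10), np.zeros(10)])
        assert len(bins) == 1
        assert bins[0][2] == 20

    def test_all_negative_labels_observed_zero(self, rng):
        p = rng.uniform(size=200)
        bins = calibration_bins(p, np.zeros(200, int))
        assert all(obs == 0.0 for _, obs, _ in bins)


class TestDecisionCurve:
    def test_treat_none_zero_and_low_threshold_limit(self):
        p = np.array([0.9, 0.8, 0.7, 0.6, 0.5])
        y = np.array([1, 1, 0, 1, 0])
        dc = decision_curve(p, y, thresholds=np.array([0.01, 0.3]))
        assert np.all(dc["treat_none"] == 0.0)
        # pt -> 0 with everyone predicted positive: NB -> prevalence
        assert dc["model"][0] == pytest.approx(0.6 - 0.4 * 0.01 / 0.99)

    def test_ten_subject_hand_computation(self):
        p = np.array([0.9, 0.8, 0.7, 0.6, 0.55, 0.4, 0.3, 0.2, 0.1, 0.05])
        y = np.array([1, 1, 0, 1, 0, 1, 0, 0, 0, 0])
        dc = decision_curve(p, y, thresholds=np.array([0.5]))
        # predicted positive: p >= 0.5 -> TP=3, FP=2; NB = 0.3 - 0.2*1 = 0.1
        assert dc["model"][0] == pytest.approx(0.3 - 0.2 * 0.5 / 0.5)
        assert dc["treat_all"][0] == pytest.approx(0.4 - 0.6 * 1.0)

    def test_net_benefit_never_exceeds_prevalence(self, rng):
        p = rng.uniform(size=100)
        y = rng.integers(0, 2, 100)
        dc = decision_curve(p, y, thresholds=np.linspace(0.05, 0.95, 19))
        assert np.all(dc["model"] <= y.mean() + 1e-12)

    def test_threshold_bounds_enforced(self):
        with pytest.raises(ValueError):
            decision_curve(np.array([0.5]), np.array([1]), np.array([1.0]))


class TestKmLogrank:
    def test_km_no_censoring_is_empirical_survival(self):
        time = np.array([1.0, 2.0, 3.0, 4.0])
        times, surv = km_curve(time, np.ones(4, int))
        for t_obs, frac in zip([1.0, 2.0, 3.0, 4.0], [0.75, 0.5, 0.25, 0.0]):
            assert surv[times == t_obs][0] == pytest.approx(frac)

    def test_identical_groups_no_difference(self):
        time = np.array([1.0, 2.0, 3.0, 5.0, 8.0])
        event = np.array([1, 0, 1, 1, 0])
        chi2, p = logrank(time, event, time, event)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_group_toy_matches_hand_table(self):
        """6+6 toy; observed-vs-expected table computed independently."""
        t_a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        e_a = np.array([1, 1, 1, 1, 0, 0])
        t_b = np.array([2.5, 3.5, 4.5, 5.5, 6.5, 7.5])
        e_b = np.array([0, 1, 0, 1, 0, 1])
        chi2, p = logrank(t_a, e_a, t_b, e_b)

        # independent O-E computation over pooled event times
        times = np.r_[t_a, t_b]
        events = np.r_[e_a, e_b]
        group = np.r_[np.zeros(6), np.ones(6)]
        o_minus_e = var = 0.0
        for t in np.unique(times[events == 1]):
            at_risk = times >= t
            d = float(((times == t) & (events == 1)).sum())
            n = float(at_risk.sum())
            n1 = float((at_risk & (group == 0)).sum())
            d1 = float(((times == t) & (events == 1) & (group == 0)).sum())
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        assert chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank(np.array([]), np.array([]), np.array([1.0]), np.array([1]))


class TestTimeDependentAuc:
    def test_uncensored_reduces_to_binary_auc(self, rng):
        time = rng.exponential(5.0, 50)
        marker = -time + rng.normal(0, 1.0, 50)
        event = np.ones(50, bool)
        horizon = float(np.median(time))
        labels = (time <= horizon).astype(int)
        assert time_dependent_auc(marker, time, event, horizon) == pytest.approx(
            roc_auc(marker, labels).auc, abs=1e-12)

    def test_independent_marker_is_chance(self, rng):
        n = 4000
        time = rng.exponential(5.0, n)
        censor = rng.uniform(0, 10, n)
        event = time <= censor
        obs = np.minimum(time, censor)
        marker = rng.normal(size=n)
        auc = time_dependent_auc(marker, obs, event, 5.0)
        assert abs(auc - 0.5) < 0.05

    def test_censored_toy_matches_weighted_pair_oracle(self):
        marker = np.array([3.0, 1.0, 2.5, 0.5, 2.0, 1.5, 2.8, 0.2])
        time = np.array([0.5, 4.0, 1.0, 5.0, 2.0, 3.0, 1.5, 6.0])
        event = np.array([1, 0, 1, 0, 0, 1, 1, 0], dtype=bool)
        horizon = 3.5
        auc = time_dependent_auc(marker, time, event, horizon)

        # independent oracle: censoring KM and explicit weighted pairs
        from lifelines import KaplanMeierFitter

        G = KaplanMeierFitter().fit(time, 1 - event.astype(int))
        num = den = 0.0
        for i in range(8):
            if not (event[i] and time[i] <= horizon):
                continue
            w = 1.0 / float(G.survival_function_at_times(time[i] - 1e-12).iloc[0])
            for j in range(8):
                if time[j] > horizon:
                    den += w
                    if marker[i] > marker[j]:
                        num += w
                    elif marker[i] == marker[j]:
                        num += 0.5 * w
        assert auc == pytest.approx(num / den, abs=1e-12)

    def test_no_events_before_horizon_rejected(self):
        with pytest.raises(ValueError):
            time_dependent_auc(np.array([1.0, 2.0]), np.array([5.0, 6.0]),
                               np.array([1, 1], dtype=bool), 1.0)


def _rank_fit(records, time, event):
    """Trivial fit procedure for bootstrap tests: risk = stored marker."""

    def score(recs, t, e):
        return np.array([r["marker"] for r in recs])

    return score


class TestBootstrapCindex:
    def test_single_resample_reproducible(self, rng):
        records = [{"marker": float(m)} for m in rng.normal(size=40)]
        time = rng.exponential(5, 40)
        event = rng.uniform(size=40) < 0.7
        event[:2] = [True, True]
        out1 = bootstrap_cindex(_rank_fit, records, time, event, B=1, seed=5)
        out2 = bootstrap_cindex(_rank_fit, records, time, event, B=1, seed=5)
        assert out1 == out2

    def test_perfect_marker_stays_perfect(self):
        time = np.linspace(1, 10, 20)
        records = [{"marker": float(-t)} for t in time]
        event = np.ones(20, bool)
        apparent, corrected = bootstrap_cindex(
            _rank_fit, records, time, event, B=20, seed=0)
        assert apparent == 1.0
        assert corrected == pytest.approx(1.0)

    def test_null_marker_near_chance(self, rng):
        n = 120
        time = rng.exponential(5, n)
        event = rng.uniform(size=n) < 0.7
        event[:2] = True

        def fit_cox_noise(recs, t, e):
            x = np.array([r["noise"] for r in recs])[:, None]
            from opmdml import cox_fit

            model = cox_fit(x, t, e)

            def score(recs2, t2, e2):
                x2 = np.array([r["noise"] for r in recs2])
                return x2 * model.beta[0]

            return score

        records = [{"noise": float(v)} for v in rng.normal(size=n)]
        _, corrected = bootstrap_cindex(
            fit_cox_noise, records, time, event, B=200, seed=1)
        assert abs(corrected - 0.5) < 0.05

    def test_invalid_b_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_cindex(_rank_fit, [], np.array([]), np.array([]), B=0)
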