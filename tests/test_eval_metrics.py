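"""Metric implementations versus brute-force and library oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import average_precision_score, roc_auc_score

from facerisk import eval_metrics as em


def brute_force_auc(scores, labels):
    """O(n^2) concordant-pair count with half credit for ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_hand_counted_example(self):
        assert em.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_and_tied(self):
        assert em.auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert em.auc([5, 5, 5, 5], [0, 0, 1, 1]) == 0.5

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_equals_brute_force_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        y = np.r_[np.ones(2), np.zeros(2), rng.integers(0, 2, n - 4)]
        scores = rng.integers(0, 8, n).astype(float)  # integer scores force ties
        assert em.auc(scores, y) == pytest.approx(brute_force_auc(scores, y), abs=1e-12)

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 300)
        y[:2] = [0, 1]
        s = rng.normal(size=300)
        assert em.auc(s, y) == pytest.approx(roc_auc_score(y, s))

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            em.auc([0.1, 0.2], [1, 1])


class TestAveragePrecision:
    def test_perfect_ordering(self):
        assert em.average_precision([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_positive_ranked_first(self):
        assert em.average_precision([0.9, 0.5, 0.4, 0.3], [1, 0, 0, 0]) == 1.0

    def test_matches_sklearn(self, rng):
        y = rng.integers(0, 2, 400)
        y[:2] = [0, 1]
        s = rng.normal(size=400)
        assert em.average_precision(s, y) == pytest.approx(average_precision_score(y, s))

    def test_null_scores_approach_prevalence(self, rng):
        y = (rng.random(20000) < 0.3).astype(int)
        s = rng.random(20000)
        assert em.average_precision(s, y) == pytest.approx(0.3, abs=0.02)


class TestBrier:
    def test_closed_forms(self):
        assert em.brier([1.0, 0.0], [1, 0]) == 0.0
        assert em.brier([0.5, 0.5], [1, 0]) == 0.25

    def test_constant_prevalence_forecast(self, rng):
        y = (rng.random(50000) < 0.2).astype(int)
        assert em.brier(np.full(50000, 0.2), y) == pytest.approx(0.2 * 0.8, abs=0.005)


class TestCalibration:
    def test_perfectly_calibrated_bins_give_zero_statistic(self):
        probs = np.repeat([0.2, 0.4, 0.6, 0.8], 10)
        labels = np.concatenate([[1] * int(p * 10) + [0] * (10 - int(p * 10))
                                 for p in (0.2, 0.4, 0.6, 0.8)])
        c = em.calibration(probs, labels, n_bins=4)
        assert c.hl_statistic == pytest.approx(0.0, abs=1e-9)

    def test_all_positive_labels(self):
        c = em.calibration(np.full(100, 0.5), np.r_[np.ones(99), [0]], n_bins=5)
        assert c.observed_rate.max() > 0.9

    def test_duplicate_edges_merge_flagged(self):
        probs = np.r_[np.full(50, 0.3), np.full(50, 0.7)]
        labels = np.resize([0, 1], 100)
        c = em.calibration(probs, labels, n_bins=10)
        assert c.merged_bins

    def test_fitted_flag_reduces_df_by_two(self, rng):
        p = rng.uniform(0.1, 0.9, 500)
        y = (rng.random(500) < p).astype(int)
        external = em.calibration(p, y)
        fitted = em.calibration(p, y, fitted=True)
        assert external.hl_df == fitted.hl_df + 2


class TestDecisionCurve:
    def test_treat_none_identically_zero(self, rng):
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        d = em.decision_curve(rng.random(200), y)
        assert np.all(d.treat_none == 0.0)

    def test_perfect_classifier_net_benefit_is_prevalence(self):
        y = np.resize([0, 1], 100)
        d = em.decision_curve(y.astype(float), y)
        assert np.allclose(d.net_benefit, 0.5)

    def test_treat_all_crosses_zero_at_prevalence(self, rng):
        y = (rng.random(1000) < 0.3).astype(int)
        pi = y.mean()
        d = em.decision_curve(rng.random(1000), y, thresholds=np.r_[pi, 0.1, 0.5])
        at_pi = d.treat_all[d.thresholds == pi]
        assert at_pi == pytest.approx(0.0, abs=1e-12)

    def test_model_nb_bounded_by_prevalence(self, rng):
        y = rng.integers(0, 2, 500)
        y[:2] = [0, 1]
        d = em.decision_curve(rng.random(500), y)
        assert np.all(d.net_benefit <= y.mean() + 1e-12)


def brute_force_delong(sa, sb, y):
    """Structural components by explicit double loops (oracle)."""
    sa, sb, y = map(np.asarray, (sa, sb, y))
    out = {}
    for tag, s in (("a", sa), ("b", sb)):
        pos = s[y == 1]
        neg = s[y == 0]
        psi = (pos[:, None] > neg[None, :]) + 0.5 * (pos[:, None] == neg[None, :])
        out[tag] = psi
    va, vb = out["a"], out["b"]
    m, n = va.shape
    auc_a, auc_b = va.mean(), vb.mean()
    v10 = np.vstack([va.mean(1), vb.mean(1)])
    v01 = np.vstack([va.mean(0), vb.mean(0)])
    s10 = np.cov(v10, ddof=1)
    s01 = np.cov(v01, ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    return auc_a, auc_b, var


class TestDeLong:
    def test_model_vs_itself(self):
        r = em.delong([0.9, 0.8, 0.2, 0.1], [0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.p == 1.0 and r.degenerate
        assert r.difference == 0.0

    def test_four_sample_case_matches_brute_force(self):
        y = [1, 1, 0, 0]
        a = [0.9, 0.8, 0.2, 0.1]
        b = [0.9, 0.2, 0.8, 0.1]
        r = em.delong(a, b, y)
        auc_a, auc_b, var = brute_force_delong(a, b, y)
        assert r.auc_a == pytest.approx(auc_a)
        assert r.auc_b == pytest.approx(auc_b)
        assert r.variance == pytest.approx(var, abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_components_match_brute_force_randomized(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 40))
        y = np.r_[1, 1, 0, 0, rng.integers(0, 2, n - 4)]
        a = rng.integers(0, 6, n).astype(float)
        b = rng.integers(0, 6, n).astype(float)
        r = em.delong(a, b, y)
        auc_a, auc_b, var = brute_force_delong(a, b, y)
        assert r.auc_a == pytest.approx(auc_a, abs=1e-12)
        assert r.auc_b == pytest.approx(auc_b, abs=1e-12)
        assert r.variance == pytest.approx(var, abs=1e-12)

    def test_auc_agrees_with_auc_function(self, rng):
        y = rng.integers(0, 2, 150)
        y[:2] = [0, 1]
        a, b = rng.normal(size=150), rng.normal(size=150)
        r = em.delong(a, b, y)
        assert r.auc_a == pytest.approx(em.auc(a, y))
        assert r.auc_b == pytest.approx(em.auc(b, y))


class TestEvaluate:
    def test_internal_identities(self, rng):
        y = rng.integers(0, 2, 400)
        y[:2] = [0, 1]
        p = np.clip(rng.normal(0.5, 0.25, 400), 0, 1)
        rep = em.evaluate_probs(p, y)
        cm = rep.confusion
        n = sum(cm.values())
        assert rep.accuracy == pytest.approx((cm["TP"] + cm["TN"]) / n)
        assert rep.sensitivity == pytest.approx(cm["TP"] / (cm["TP"] + cm["FN"]))
        assert rep.specificity == pytest.approx(cm["TN"] / (cm["TN"] + cm["FP"]))
        if rep.precision + rep.sensitivity > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.sensitivity / (rep.precision + rep.sensitivity)
            )
        assert 0 <= rep.brier <= 1

    def test_separable_data_perfect_metrics(self):
        y = np.resize([0, 1], 50)
        rep = em.evaluate_probs(np.where(y == 1, 0.99, 0.01), y)
        assert rep.accuracy == 1.0
        assert rep.auc == 1.0
        assert rep.brier == pytest.approx(0.0001)


class TestGroupChi2:
    def test_matches_hand_pearson(self):
        # Pearson chi-square on a 2x2 table, no correction
        table = [[550, 566], [725, 458]]
        stat, p = em.group_chi2(table)
        obs = np.asarray(table, dtype=float)
        exp = obs.sum(1)[:, None] * obs.sum(0)[None, :] / obs.sum()
        assert stat == pytest.approx(((obs - exp) ** 2 / exp).sum())
        assert p < 0.001
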