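import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import imlgam as im


def brute_force_youden(score, y):
    uniq = np.unique(score)
    candidates = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    best_t, best_j = None, -np.inf
    for t in candidates:
        pred = score < t
        tpr = np.sum(pred & (y == 1)) / np.sum(y == 1)
        tnr = np.sum(~pred & (y == 0)) / np.sum(y == 0)
        if tpr + tnr - 1 > best_j + 1e-12:
            best_t, best_j = t, tpr + tnr - 1
    return best_t, best_j


class TestYoudenThreshold:
    def test_separable_case_midpoint(self):
        score = np.array([0.1, 0.2, 0.8, 0.9])
        y = np.array([1, 1, 0, 0])
        assert im.youden_threshold(score, y) == pytest.approx(0.5)

    def test_all_equal_scores_returns_sentinel(self):
        score = np.ones(6)
        y = np.array([1, 0, 1, 0, 1, 0])
        t = im.youden_threshold(score, y)
        assert t == -np.inf  # everyone predicted non-responder
        assert not np.any(score < t)

    def test_matches_exhaustive_oracle(self, rng):
        for _ in range(20):
            n = 50
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            score = rng.normal(size=n) - y  # responders lower on average
            t_oracle, j_oracle = brute_force_youden(score, y)
            t = im.youden_threshold(score, y)
            assert t == t_oracle
            pred = score < t
            j = np.sum(pred & (y == 1)) / np.sum(y == 1) + np.sum(~pred & (y == 0)) / np.sum(y == 0) - 1
            assert j == pytest.approx(j_oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            im.youden_threshold(np.arange(4.0), np.zeros(4, dtype=int))


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1, 0, 1, 0])
        m = im.confusion_metrics(y, y)
        assert (m.tpr, m.tnr, m.f1, m.fpr, m.fnr) == (1.0, 1.0, 1.0, 0.0, 0.0)

    def test_hand_computed_table(self):
        m = im.confusion_metrics(np.array([1, 1, 0, 0]), np.array([1, 0, 1, 0]))
        assert m.tpr == 0.5 and m.tnr == 0.5 and m.f1 == 0.5
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 1, 1, 1)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=4, max_size=60))
    def test_rate_identities(self, rows):
        pred = np.array([a for a, _ in rows])
        y = np.array([b for _, b in rows])
        m = im.confusion_metrics(pred, y)
        assert m.tp + m.fp + m.tn + m.fn == len(rows)
        if np.isfinite(m.tpr):
            assert m.tpr + m.fnr == pytest.approx(1.0)
        if np.isfinite(m.tnr):
            assert m.tnr + m.fpr == pytest.approx(1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="equal lengths"):
            im.confusion_metrics(np.array([1]), np.array([1, 0]))


class TestKMLogrank:
    def test_identical_groups_null(self):
        t = np.array([3.0, 5.0, 7.0, 9.0] * 2)
        e = np.array([1, 0, 1, 1] * 2)
        g = np.array([0] * 4 + [1] * 4)
        res = im.km_logrank(t, e, g)
        assert res.chi_square == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_hand_computed_ten_subject_fixture(self):
        # O1 = 4, E1 = 5.4031746, V = 0.9998841 -> chi2 = 1.9691272
        # (direct hypergeometric computation, confirmed against survdiff in R)
        t = np.array([5, 6, 6, 8, 10, 12, 12, 15, 20, 24], dtype=float)
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1, 0, 1])
        g = np.array([0, 0, 0, 0, 1, 0, 1, 1, 1, 1])
        res = im.km_logrank(t, e, g)
        assert res.chi_square == pytest.approx(1.9691271853, abs=1e-6)
        assert res.p_value == pytest.approx(0.1605405368, abs=1e-6)
        assert res.n_group0 == 5 and res.n_group1 == 5

    def test_km_curve_shape(self):
        t = np.array([2.0, 4.0, 6.0, 8.0, 10.0, 12.0])
        e = np.array([1, 1, 0, 1, 1, 0])
        g = np.array([0, 0, 0, 1, 1, 1])
        res = im.km_logrank(t, e, g)
        for curve in res.km_curves.values():
            s = curve["survival"].to_numpy()
            assert s[0] == 1.0
            assert np.all(np.diff(s) <= 1e-12)  # non-increasing

    def test_all_censored_is_error(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        e = np.zeros(4, dtype=int)
        g = np.array([0, 0, 1, 1])
        with pytest.raises(ValueError, match="no events"):
            im.km_logrank(t, e, g)


class TestEvaluateScores:
    def test_auc_orientation_identity(self, rng):
        y = rng.integers(0, 2, size=60)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        score = rng.normal(size=60)
        auc_low = im.pair_auc(-score, y)
        assert auc_low == pytest.approx(1 - im.pair_auc(score, y), abs=1e-12)
        m = im.evaluate_scores(score, y, threshold=0.0)
        assert m.auc == pytest.approx(auc_low, abs=1e-12)

    def test_counts_sum_to_n(self, rng):
        y = np.array([1, 0] * 15)
        score = rng.normal(size=30)
        m = im.evaluate_scores(score, y, threshold=float(np.median(score)))
        assert m.tp + m.fp + m.tn + m.fn == 30
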