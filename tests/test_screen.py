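import numpy as np
import pytest
import statsmodels.api as sm

import imlgam as im
from imlgam.screen import FLAG_FAILED, FLAG_OK, FLAG_SEPARATION


def brute_force_auc(x, y):
    """Direct Mann-Whitney count over all positive-negative pairs."""
    pos = x[y == 1]
    neg = x[y == 0]
    wins = sum(1.0 for a in pos for b in neg if a > b)
    ties = sum(1.0 for a in pos for b in neg if a == b)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestPairAuc:
    def test_perfect_ranking(self):
        y = np.array([1, 1, 0, 0])
        assert im.pair_auc(y.astype(float), y) == 1.0

    def test_constant_is_half(self):
        assert im.pair_auc(np.ones(6), np.array([1, 1, 1, 0, 0, 0])) == 0.5

    def test_worked_tie_example(self):
        # 4 wins + 2 ties of 6 comparisons -> 5/6
        y = np.array([1, 1, 1, 0, 0])
        x = np.array([1, 1, 0, 0, 0], dtype=float)
        assert im.pair_auc(x, y) == pytest.approx(5 / 6, abs=1e-15)

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            n = int(rng.integers(6, 60))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            x = rng.integers(0, 4, size=n).astype(float)  # discrete: many ties
            assert im.pair_auc(x, y) == pytest.approx(brute_force_auc(x, y), abs=1e-12)

    def test_binary_classifier_identity(self, rng):
        """For binary x, AUC = (sensitivity + specificity) / 2."""
        for _ in range(20):
            n = int(rng.integers(10, 80))
            y = rng.integers(0, 2, size=n)
            x = rng.integers(0, 2, size=n).astype(float)
            if y.min() == y.max():
                continue
            sens = np.sum((x == 1) & (y == 1)) / np.sum(y == 1)
            spec = np.sum((x == 0) & (y == 0)) / np.sum(y == 0)
            assert im.pair_auc(x, y) == pytest.approx((sens + spec) / 2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            im.pair_auc(np.arange(4.0), np.ones(4, dtype=int))


class TestAdjustedLogistic:
    def test_matches_statsmodels_oracle(self):
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1, 1, 0, 0, 1])
        x = np.array([0, 0, 1, 1, 0, 1, 1, 0, 0, 1, 1, 0], dtype=float)
        ct = ["m"] * 12
        coef, se, p, flag = im.fit_logistic_adjusted(x, y, ct)
        X = sm.add_constant(x)
        fit = sm.Logit(y, X).fit(disp=0)
        assert flag == FLAG_OK
        assert coef == pytest.approx(fit.params[1], abs=1e-8)
        assert se == pytest.approx(fit.bse[1], abs=1e-8)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_adjustment_with_dummies_matches_statsmodels(self, rng):
        n = 90
        ct = np.array(["a", "b", "c"])[rng.integers(0, 3, size=n)]
        x = rng.integers(0, 2, size=n).astype(float)
        logits = -0.3 + 0.8 * x + 0.6 * (ct == "b") - 0.4 * (ct == "c")
        y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
        coef, se, p, flag = im.fit_logistic_adjusted(x, y, ct)
        X = np.column_stack([np.ones(n), x, (ct == "b").astype(float), (ct == "c").astype(float)])
        fit = sm.Logit(y, X).fit(disp=0)
        assert flag == FLAG_OK
        assert coef == pytest.approx(fit.params[1], abs=1e-8)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_complete_separation_triggers_firth(self):
        y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
        x = y.astype(float)
        coef, se, p, flag = im.fit_logistic_adjusted(x, y, ["m"] * 8)
        assert flag == FLAG_SEPARATION
        assert np.isfinite(coef) and abs(coef) < 10
        assert np.isfinite(p)

    def test_cancer_type_confounding_is_absorbed(self, rng):
        """A feature tracking cancer type loses significance once adjusted."""
        n = 120
        ct = np.array(["hot"] * 60 + ["cold"] * 60)
        y = np.concatenate([rng.random(60) < 0.6, rng.random(60) < 0.15]).astype(int)
        x = (ct == "hot").astype(float)
        flips = rng.choice(n, size=6, replace=False)
        x[flips] = 1 - x[flips]  # nearly collinear with type, not exactly
        # unadjusted: x looks strongly predictive
        _, _, p_unadj, _ = im.fit_logistic_adjusted(x, y, ["one"] * n)
        coef, se, p_adj, flag = im.fit_logistic_adjusted(x, y, ct)
        assert p_unadj < 0.001
        assert p_adj > 0.05
        # oracle agreement on the adjusted fit
        X = np.column_stack([np.ones(n), x, (ct == "hot").astype(float)])
        fit = sm.Logit(y, X).fit(disp=0)
        assert p_adj == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_single_class_y_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            im.fit_logistic_adjusted(np.array([0.0, 1.0]), np.array([1, 1]), ["m", "m"])


class TestScreenPairs:
    def test_planted_pair_passes_noise_mostly_fails(self):
        ds = im.generate(im.SynthConfig(n_samples=600, n_genes=30, planted_pairs=2,
                                        pi1=0.95, pi0=0.05, seed=4))
        pairs = im.enumerate_pairs(ds.expression.gene_ids, ds.expression)
        F = im.drop_degenerate(im.pair_features(ds.expression, pairs))
        res = im.screen_pairs(F, ds.clinical.response, ds.clinical.cancer_type)
        planted = {(p.gene_a, p.gene_b) for p in ds.truth.planted_pairs}
        got = set(zip(res.loc[res["pass"], "gene_a"], res.loc[res["pass"], "gene_b"]))
        assert planted <= got

    def test_constant_pair_flagged_failed(self):
        F = im.PairFeatureMatrix(
            pairs=[im.GenePair("A", "B")],
            sample_ids=[f"s{i}" for i in range(8)],
            values=np.zeros((1, 8), dtype=np.uint8),
        )
        y = np.array([0, 1, 0, 1, 0, 1, 0, 1])
        res = im.screen_pairs(F, y, ["m"] * 8)
        assert res.loc[0, "flag"] == FLAG_FAILED
        assert not res.loc[0, "pass"]

    def test_screening_invariant_to_distortion(self):
        base = im.SynthConfig(n_samples=200, n_genes=16, planted_pairs=2,
                              batch_distortion="none", seed=6)
        ds0 = im.generate(base)
        ds1 = im.generate(im.SynthConfig(n_samples=200, n_genes=16, planted_pairs=2,
                                         batch_distortion="power", seed=6))
        pairs = im.enumerate_pairs(ds0.expression.gene_ids, ds0.expression)
        F0 = im.pair_features(ds0.expression, pairs)
        F1 = im.pair_features(ds1.expression, pairs)
        np.testing.assert_array_equal(F0.values, F1.values)
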