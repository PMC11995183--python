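import itertools

import numpy as np
import pytest
from scipy.special import expit

import imlgam as im
from imlgam._logistic import fit_irls, intercept_only_nll


def exhaustive_aic(Z, y):
    """Best subset of candidate columns by AIC, enumerating all subsets."""
    n, p = Z.shape
    best, best_aic = (), np.inf
    for r in range(p + 1):
        for cols in itertools.combinations(range(p), r):
            if cols:
                X = np.column_stack([np.ones(n), Z[:, list(cols)]])
                nll = fit_irls(X, y, max_iter=50).nll
            else:
                nll = intercept_only_nll(y)
            aic = 2 * nll + 2 * (len(cols) + 1)
            if aic < best_aic - 1e-10:
                best, best_aic = cols, aic
    return set(best)


def stacked_fixture(rng, n=150, informative=True):
    Z = rng.normal(size=(n, 3))
    logits = (2.0 * Z[:, 1] if informative else np.zeros(n)) - 0.2
    y = (rng.random(n) < expit(logits)).astype(int)
    return Z, y


class TestStepwiseLogistic:
    def test_pure_noise_gives_intercept_only(self):
        rng = np.random.default_rng(6)
        Z, y = stacked_fixture(rng, n=400, informative=False)
        sm = im.stepwise_logistic(Z, y)
        assert sm.member_ids == []
        prevalence_logit = np.log(y.mean() / (1 - y.mean()))
        assert sm.intercept == pytest.approx(prevalence_logit, abs=1e-6)

    def test_matches_exhaustive_aic_subsets(self):
        for seed in range(3):
            rng = np.random.default_rng(500 + seed)
            Z, y = stacked_fixture(rng)
            sm = im.stepwise_logistic(Z, y, ["c0", "c1", "c2"])
            got = {int(m[1]) for m in sm.member_ids}
            assert got == exhaustive_aic(Z, y)

    def test_duplicated_column_kept_once(self):
        rng = np.random.default_rng(9)
        z = rng.normal(size=200)
        y = (rng.random(200) < expit(2 * z)).astype(int)
        Z = np.column_stack([z, z])
        sm = im.stepwise_logistic(Z, y, ["first", "copy"])
        assert sm.member_ids == ["first"]

    def test_nonfinite_rejected(self):
        Z = np.array([[1.0], [np.inf]])
        with pytest.raises(ValueError, match="non-finite"):
            im.stepwise_logistic(Z, np.array([0, 1]))


class TestFitness:
    def test_empty_chromosome_is_zero(self, rng):
        Z = rng.normal(size=(40, 4))
        y = np.array([0, 1] * 20)
        assert im.fitness(np.zeros(4, dtype=int), Z, y) == 0.0

    def test_perfect_column_scores_one(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, size=60)
        Z = np.column_stack([y.astype(float), rng.normal(size=60)])
        bits = np.array([1, 0])
        assert im.fitness(bits, Z, y, inner_k=3, seed=0) == 1.0

    def test_deterministic_under_seed(self, rng):
        Z = rng.normal(size=(80, 5))
        y = rng.integers(0, 2, size=80)
        bits = np.array([1, 0, 1, 1, 0])
        a = im.fitness(bits, Z, y, inner_k=4, seed=11)
        b = im.fitness(bits, Z, y, inner_k=4, seed=11)
        assert a == b


@pytest.fixture(scope="module")
def ga_problem():
    rng = np.random.default_rng(15)
    n, p = 200, 12
    good = rng.normal(size=n)
    y = (rng.random(n) < expit(1.5 * good)).astype(int)
    Z = rng.normal(size=(n, p))
    Z[:, 2] = good + 0.4 * rng.normal(size=n)
    Z[:, 7] = good + 0.6 * rng.normal(size=n)
    return Z, y


class TestGASelect:
    def test_trace_non_decreasing_and_dominates_seeds(self, ga_problem):
        Z, y = ga_problem
        ga = im.GAConfig(population=12, generations=6, patience=3, seed=21)
        bits, trace = im.ga_select(Z, y, ga=ga, inner_k=3)
        assert all(b >= a for a, b in zip(trace, trace[1:]))
        best = trace[-1]
        all_ones = im.fitness(np.ones(Z.shape[1], dtype=int), Z, y, inner_k=3, seed=21)
        assert best >= all_ones - 1e-12
        singles = []
        for j in np.argsort([-im.pair_auc(Z[:, j], y) for j in range(Z.shape[1])])[:5]:
            c = np.zeros(Z.shape[1], dtype=int)
            c[j] = 1
            singles.append(im.fitness(c, Z, y, inner_k=3, seed=21))
        assert best >= max(singles) - 1e-12

    def test_bit_identical_rerun(self, ga_problem):
        Z, y = ga_problem
        ga = im.GAConfig(population=12, generations=5, patience=3, seed=33)
        bits1, trace1 = im.ga_select(Z, y, ga=ga, inner_k=3)
        bits2, trace2 = im.ga_select(Z, y, ga=im.GAConfig(population=12, generations=5, patience=3, seed=33), inner_k=3)
        np.testing.assert_array_equal(bits1, bits2)
        assert trace1 == trace2

    def test_population_too_small_rejected(self, ga_problem):
        Z, y = ga_problem
        with pytest.raises(ValueError, match="population"):
            im.ga_select(Z, y, ga=im.GAConfig(population=4, elitism=2, seed=0))


class TestEndToEndModel:
    def test_orientation_low_score_means_responder(self, trained_model, planted_dataset):
        scores = trained_model.score(planted_dataset.expression)
        r = planted_dataset.clinical.response
        assert scores[r == 1].mean() < scores[r == 0].mean()

    def test_scores_invariant_to_monotone_distortion(self, trained_model, planted_dataset):
        expr = planted_dataset.expression
        rng = np.random.default_rng(0)
        a = rng.uniform(0.5, 2.0, size=expr.n_samples)
        b = rng.uniform(0.0, 1.0, size=expr.n_samples)
        distorted = im.ExpressionMatrix(
            gene_ids=list(expr.gene_ids),
            sample_ids=list(expr.sample_ids),
            values=expr.values * a[None, :] + b[None, :],
        )
        np.testing.assert_array_equal(
            trained_model.score(expr), trained_model.score(distorted)
        )

    def test_selected_pairs_are_mostly_planted(self, trained_model, planted_dataset):
        planted = {p.name for p in planted_dataset.truth.planted_pairs}
        selected = {p.name for p in trained_model.pairs}
        assert len(selected & planted) >= 3

    def test_classify_uses_threshold(self, trained_model, planted_dataset):
        scores = trained_model.score(planted_dataset.expression)
        cls = trained_model.classify(scores)
        np.testing.assert_array_equal(cls, (scores < trained_model.threshold).astype(int))
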