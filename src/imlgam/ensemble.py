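"""Ensemble assembly: stepwise-logistic stacking, GA member selection, scoring.

The out-of-fold prediction matrix Z (samples x learners) is the stacking
feature space. A binary chromosome over the learner grid selects candidate
columns; a bidirectional stepwise logistic regression (AIC) combines them
into a meta-model; a genetic algorithm searches chromosome space with the
inner-cross-validated AUC of that stacked model as fitness. The final
score is the *negated* stacked linear predictor, so lower scores indicate
a higher likelihood of responding to checkpoint blockade.

Fitness is evaluated on inner-CV held-out stacked predictions rather than
training AUC: under stepwise fitting the training AUC is monotone in
chromosome size and would collapse the search toward the full ensemble.
Training-AUC fitness remains available via ``fitness_mode="train"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._logistic import fit_irls, intercept_only_nll
from .learners import LearnerConfig, OOFMatrix, fit_oof, predict_base
from .pairs import GenePair, PairFeatureMatrix, drop_degenerate, enumerate_pairs, pair_features
from .screen import pair_auc, screen_pairs
from .subset import select_support_size

ORIENTATION = "low_score_responder"


@dataclass
class GAConfig:
    population: int = 40
    generations: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float | None = None  # default 1/n_bits
    tournament_size: int = 3
    elitism: int = 2
    patience: int = 10
    seed: int = 0

    def validate(self, n_bits: int) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        if self.elitism >= self.population:
            raise ValueError("elitism must be smaller than the population")
        if self.population < 6 + self.elitism:
            raise ValueError(
                "population too small for the seeded individuals plus elites"
            )
        for p in (self.crossover_prob, self.mutation_prob or 0.0):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.generations < 1 or self.tournament_size < 1:
            raise ValueError("generations and tournament_size must be >= 1")


@dataclass
class StackedModel:
    """Stepwise-selected meta-model: intercept + coefficient per retained member."""

    member_ids: list[str]
    intercept: float
    coefficients: dict[str, float]

    def linear_predictor(self, base_preds: np.ndarray, learner_ids: list[str]) -> np.ndarray:
        """Stacked log-odds of response from base predictions (samples x learners)."""
        col = {lid: j for j, lid in enumerate(learner_ids)}
        lp = np.full(base_preds.shape[0], self.intercept)
        for lid, beta in self.coefficients.items():
            lp = lp + beta * base_preds[:, col[lid]]
        return lp


@dataclass
class IMLGAMModel:
    """End-to-end trained bundle; ``predict`` honors low-score = responder."""

    pairs: list[GenePair]
    grid: list[LearnerConfig]
    full_fits: dict
    chromosome: np.ndarray
    stacked: StackedModel
    threshold: float
    orientation: str = ORIENTATION
    metadata: dict = field(default_factory=dict)

    def score(self, expr) -> np.ndarray:
        """Score new samples from an ExpressionMatrix (lower = more likely responder)."""
        F = pair_features(expr, self.pairs).samples_by_pairs()
        base = predict_base(self.full_fits, self.grid, F)
        return assemble_and_score(self.stacked, base, [c.id for c in self.grid])

    def classify(self, scores: np.ndarray) -> np.ndarray:
        """1 = predicted responder (score strictly below the frozen threshold)."""
        return (np.asarray(scores) < self.threshold).astype(int)


# ---------------------------------------------------------------------------
# Stepwise logistic stacking
# ---------------------------------------------------------------------------

def _aic_fit(Z: np.ndarray, y: np.ndarray, cols: tuple[int, ...]) -> tuple[float, np.ndarray]:
    n = Z.shape[0]
    if not cols:
        nll = intercept_only_nll(y)
        ybar = float(np.mean(y))
        b0 = np.log(ybar / (1 - ybar)) if 0 < ybar < 1 else 0.0
        return 2 * nll + 2.0, np.array([b0])
    X = np.column_stack([np.ones(n), Z[:, list(cols)]])
    fit = fit_irls(X, y, max_iter=50)
    return 2 * fit.nll + 2.0 * (len(cols) + 1), fit.beta


def stepwise_logistic(
    Z: np.ndarray,
    y: np.ndarray,
    column_ids: list[str] | None = None,
) -> StackedModel:
    """Bidirectional stepwise logistic regression by AIC from the empty model.

    At each step the single add or drop with the largest AIC decrease is
    applied (ties toward the smaller column index, adds before drops); the
    search stops when no move improves AIC. Deterministic.
    """
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=int)
    if Z.ndim != 2 or Z.shape[0] != y.size or Z.shape[1] < 1:
        raise ValueError("Z must be samples x candidates aligned with y")
    if not np.all(np.isfinite(Z)):
        raise ValueError("candidate matrix has non-finite entries")
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class")
    p = Z.shape[1]
    if column_ids is None:
        column_ids = [str(j) for j in range(p)]

    current: list[int] = []
    aic, beta = _aic_fit(Z, y, tuple(current))
    while True:
        best_move: tuple[str, int] | None = None
        best_aic = aic
        best_beta = beta
        for j in range(p):  # adds, smallest index first
            if j in current:
                continue
            cand = tuple(sorted(current + [j]))
            a, b = _aic_fit(Z, y, cand)
            if a < best_aic - 1e-10:
                best_move, best_aic, best_beta = ("add", j), a, b
        for j in current:  # drops
            cand = tuple(sorted(set(current) - {j}))
            a, b = _aic_fit(Z, y, cand)
            if a < best_aic - 1e-10:
                best_move, best_aic, best_beta = ("drop", j), a, b
        if best_move is None:
            break
        kind, j = best_move
        if kind == "add":
            current = sorted(current + [j])
        else:
            current = sorted(set(current) - {j})
        aic, beta = best_aic, best_beta

    member_ids = [column_ids[j] for j in current]
    coefficients = {column_ids[j]: float(beta[k + 1]) for k, j in enumerate(current)}
    return StackedModel(
        member_ids=member_ids, intercept=float(beta[0]), coefficients=coefficients
    )


# ---------------------------------------------------------------------------
# GA over chromosomes
# ---------------------------------------------------------------------------

def fitness(
    bits: np.ndarray,
    Z: np.ndarray,
    y: np.ndarray,
    inner_k: int = 5,
    seed: int = 0,
    fitness_mode: str = "cv",
) -> float:
    """AUC fitness of one chromosome; 0 for the empty chromosome.

    "cv": mean held-out AUC over inner_k stratified folds — in each fold
    the stepwise stack is fit on the training part of the chromosome's OOF
    columns and scored on the held-out part. "train": training AUC of one
    stepwise fit (kept for fidelity experiments).
    """
    bits = np.asarray(bits, dtype=int)
    Z = np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=int)
    cols = np.flatnonzero(bits)
    if cols.size == 0:
        return 0.0
    Zc = Z[:, cols]
    ids = [str(j) for j in cols]
    if fitness_mode == "train":
        sm = stepwise_logistic(Zc, y, ids)
        lp = sm.linear_predictor(Zc, ids)
        return _safe_auc(lp, y)
    skf = StratifiedKFold(n_splits=inner_k, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in skf.split(Zc, y):
        sm = stepwise_logistic(Zc[train_idx], y[train_idx], ids)
        lp = sm.linear_predictor(Zc[test_idx], ids)
        aucs.append(_safe_auc(lp, y[test_idx]))
    return float(np.mean(aucs))


def _safe_auc(lp: np.ndarray, y: np.ndarray) -> float:
    if len(np.unique(y)) < 2:
        return 0.5
    return pair_auc(lp, y)


def ga_select(
    Z: OOFMatrix | np.ndarray,
    y: np.ndarray,
    ga: GAConfig | None = None,
    inner_k: int = 5,
    fitness_mode: str = "cv",
) -> tuple[np.ndarray, list[float]]:
    """Search learner subsets by GA; returns (best chromosome, best-fitness trace).

    Generation 0 seeds the all-ones chromosome and the top-5 single-learner
    chromosomes by individual OOF AUC; the rest is random with set-bit
    probability 0.3. Tournament selection, single-point crossover, per-bit
    mutation and elitism; stops at ``generations`` or after ``patience``
    generations without a best-ever improvement.
    """
    if ga is None:
        ga = GAConfig()
    Zv = Z.values if isinstance(Z, OOFMatrix) else np.asarray(Z, dtype=float)
    y = np.asarray(y, dtype=int)
    n_bits = Zv.shape[1]
    ga.validate(n_bits)
    mut_p = ga.mutation_prob if ga.mutation_prob is not None else 1.0 / n_bits
    rng = np.random.default_rng(ga.seed)
    cache: dict[bytes, float] = {}

    def fit_of(bits: np.ndarray) -> float:
        key = bits.tobytes()
        if key not in cache:
            cache[key] = fitness(bits, Zv, y, inner_k=inner_k, seed=ga.seed, fitness_mode=fitness_mode)
        return cache[key]

    # generation 0
    pop = [np.ones(n_bits, dtype=np.uint8)]
    single_auc = np.array([_safe_auc(Zv[:, j], y) for j in range(n_bits)])
    for j in np.argsort(-single_auc, kind="stable")[:5]:
        c = np.zeros(n_bits, dtype=np.uint8)
        c[j] = 1
        pop.append(c)
    while len(pop) < ga.population:
        pop.append((rng.random(n_bits) < 0.3).astype(np.uint8))

    fits = np.array([fit_of(c) for c in pop])
    best_idx = int(np.argmax(fits))
    best_bits, best_fit = pop[best_idx].copy(), float(fits[best_idx])
    trace = [best_fit]
    stall = 0

    for _gen in range(1, ga.generations):
        order = np.argsort(-fits, kind="stable")
        new_pop = [pop[i].copy() for i in order[: ga.elitism]]
        while len(new_pop) < ga.population:
            parents = []
            for _ in range(2):
                contenders = rng.integers(0, ga.population, size=ga.tournament_size)
                winner = contenders[int(np.argmax(fits[contenders]))]
                parents.append(pop[winner])
            c1, c2 = parents[0].copy(), parents[1].copy()
            if rng.random() < ga.crossover_prob and n_bits > 1:
                cut = int(rng.integers(1, n_bits))
                c1[cut:], c2[cut:] = parents[1][cut:], parents[0][cut:]
            for child in (c1, c2):
                flip = rng.random(n_bits) < mut_p
                child[flip] ^= 1
                if len(new_pop) < ga.population:
                    new_pop.append(child)
        pop = new_pop
        fits = np.array([fit_of(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if float(fits[gen_best]) > best_fit:
            best_bits, best_fit = pop[gen_best].copy(), float(fits[gen_best])
            stall = 0
        else:
            stall += 1
        trace.append(best_fit)
        if stall >= ga.patience:
            break
    return best_bits.astype(int), trace


def assemble_and_score(
    stacked: StackedModel, base_preds: np.ndarray, learner_ids: list[str]
) -> np.ndarray:
    """Final score = negated stacked linear predictor (lower = responder)."""
    return -stacked.linear_predictor(np.asarray(base_preds, dtype=float), learner_ids)


# ---------------------------------------------------------------------------
# End-to-end training
# ---------------------------------------------------------------------------

def train(
    expr,
    clinical,
    gene_list: list[str],
    grid: list[LearnerConfig] | None = None,
    p_thresh: float = 0.001,
    auc_thresh: float = 0.6,
    s_max: int = 10,
    fixed_s: int | None = None,
    k_folds: int = 10,
    ga: GAConfig | None = None,
    inner_k: int = 5,
    seed: int = 0,
) -> IMLGAMModel:
    """Run the full training pipeline on one cohort.

    Stages: pair enumeration -> degenerate-pair drop -> adjusted-logistic +
    AUC screening -> best-subset selection (splicing, IC-tuned unless
    ``fixed_s`` pins the support size) -> stratified OOF base-learner fits
    -> GA member selection -> stepwise stacking on the OOF columns ->
    Youden threshold frozen on the training scores.

    If no pair survives screening (expected under a pure-noise cohort) the
    ``min(20, p)`` smallest-p pairs are carried forward so the downstream
    stages remain defined; held-out performance then hovers at chance.
    """
    from .evalmetrics import youden_threshold
    from .learners import default_grid

    if grid is None:
        grid = default_grid()
    if ga is None:
        ga = GAConfig(seed=seed)
    clin = clinical.reorder(expr.sample_ids)
    y = clin.response
    if len(np.unique(y)) < 2:
        raise ValueError("training response has a single class")

    all_pairs = enumerate_pairs(gene_list, expr)
    F_all = drop_degenerate(pair_features(expr, all_pairs))
    screened = screen_pairs(F_all, y, clin.cancer_type, p_thresh=p_thresh, auc_thresh=auc_thresh)
    pass_idx = np.flatnonzero(screened["pass"].to_numpy())
    fallback_screen = pass_idx.size == 0
    if fallback_screen:
        order = np.argsort(screened["p_value"].fillna(1.0).to_numpy(), kind="stable")
        pass_idx = order[: min(20, len(F_all.pairs))]
    F_scr = PairFeatureMatrix(
        pairs=[F_all.pairs[i] for i in pass_idx],
        sample_ids=list(F_all.sample_ids),
        values=F_all.values[pass_idx, :],
    )

    X = F_scr.samples_by_pairs()
    if fixed_s is not None:
        from .subset import splicing_best_subset

        support, _ = splicing_best_subset(X, y, min(fixed_s, X.shape[1]))
    else:
        support = select_support_size(X, y, s_max=min(s_max, X.shape[1])).selected_pairs
    if not support:  # IC chose the empty model; keep the single best pair
        support = [int(np.argmax(_marginal(X, y)))]
    sel_pairs = [F_scr.pairs[i] for i in support]
    F_sel = X[:, support]

    oof, full_fits = fit_oof(F_sel, y, grid=grid, k=k_folds, seed=seed)
    chromosome, trace = ga_select(oof, y, ga=ga, inner_k=inner_k)
    cols = np.flatnonzero(chromosome)
    ids = [oof.learner_ids[j] for j in cols]
    stacked = stepwise_logistic(oof.values[:, cols], y, ids)

    train_base = predict_base(full_fits, grid, F_sel)
    train_scores = assemble_and_score(stacked, train_base, oof.learner_ids)
    threshold = youden_threshold(train_scores, y)
    if not np.isfinite(threshold):
        threshold = float(np.median(train_scores))

    meta = {
        "seed": int(seed),
        "n_train": int(y.size),
        "p_thresh": p_thresh,
        "auc_thresh": auc_thresh,
        "n_candidate_pairs": int(len(F_all.pairs)),
        "n_screened_pairs": int(len(F_scr.pairs)),
        "screen_fallback": bool(fallback_screen),
        "support_size": int(len(support)),
        "ga_trace": [float(v) for v in trace],
        "ga_members": ids,
        "stacked_members": stacked.member_ids,
    }
    return IMLGAMModel(
        pairs=sel_pairs,
        grid=grid,
        full_fits=full_fits,
        chromosome=np.asarray(chromosome, dtype=int),
        stacked=stacked,
        threshold=float(threshold),
        metadata=meta,
    )


def _marginal(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    from .subset import marginal_scores

    return marginal_scores(X, y)
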