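# Methods

This note records the model, the procedure, the defaults, and the design
choices made where the design was genuinely open. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Feature space: relative-ordering gene pairs

For genes a, b and sample s the feature is `1[expr_a(s) > expr_b(s)]`, with
ties scoring 0. Strict inequality keeps the indicator well-defined on
quantized data and is the convention of relative-ordering classifiers; the
anti-symmetry `x_{(b,a)} = 1 − x_{(a,b)}` holds exactly on tie-free
samples. Because each feature depends only on a within-sample comparison,
any family of per-sample strictly increasing transforms leaves the whole
feature matrix unchanged — this is the batch-robustness claim, and it is
asserted bit-exactly in the tests rather than approximately.

The pair universe is all unordered pairs within the supplied immune gene
list that are present in the expression matrix (not immune × whole-genome);
listed genes absent from the matrix are dropped with a logged count. A
degenerate-pair filter removes constant indicator rows by default
(`min_frac = 0`); larger `min_frac` values optionally drop near-constant
pairs. This filter is plumbing, not statistics: the screening stage carries
the inferential content.

## Screening

Each pair is screened with a cancer-type-adjusted logistic regression
(treatment coding, reference level = first type in sorted order), fit by
Newton/IRLS. The gate is a two-sided Wald p-value on the pair coefficient
below 0.001 **and** a standalone feature AUC above 0.6, both strict. Choices
made here:

- **Wald, not LRT** — at 10^3–10^5 pairs per cohort the Wald test needs one
  fit per pair instead of two; the hand-rolled IRLS solver (tiny dense
  designs, ≤ ~8 columns) keeps a full screen in the low seconds. The test
  suite pins coefficients, standard errors and p-values to statsmodels to
  1e-8.
- **Separation fallback** — binary features separate easily; if IRLS fails
  to converge in 100 iterations or |b1| > 10, the pair is refit with
  Jeffreys-prior (Firth) penalization and flagged `separation_fallback`.
  The penalized estimate is finite under complete separation.
- **No multiplicity correction** — the gate is a raw p-value threshold and
  is documented as such; the null simulation in the acceptance suite checks
  the screened-pair count against the binomial upper bound this implies.
- **AUC on the feature alone**, not on the adjusted model's fitted
  probabilities (configurable reading; the feature-alone version is what the
  threshold semantics "this pair alone ranks responders" suggests).

## Best-subset selection (splicing)

For support size s the search starts from the s features with the largest
absolute standardized score statistics and repeatedly exchanges features
between active and inactive sets. Exchange candidates are ranked by
*sacrifices* computed from the current fit (backward: `b_j² · x_jᵀWx_j / 2`;
forward: the squared one-step score update scaled the same way); block
exchanges of k = 1..k_max features are tried first, and when none improves
the likelihood a single-coordinate sweep over the least-useful actives ×
most-promising inactives refines the support. Constants: `k_max = min(s, 5)`,
acceptance tolerance τ = 1e-6, at most 20 sweeps. Initialization is by
marginal ranking, so the stage is deterministic and seed-free.

Support size is tuned over s = 0..s_max (default 10) with
`IC(s) = 2·NLL(s) + s·log(p)·log(log(max(n,3)))`, ties toward smaller s; a
monotonicity guard falls back to the nested extension of the previous
support if the heuristic search ever lands above the smaller model's NLL.
Fixing s a priori is supported (`fixed_s`). An exhaustive enumerator
(`exhaustive_best_subset`) exists purely as the independent oracle for the
tests; the pipeline never calls it.

## Base-learner grid and stacking inputs

The default grid is fixed and documented: Elastic Net over mixing
{0, .25, .5, .75, 1} × penalty {.01, .1, 1} (15); Random Forest over trees
{100, 500} × feature fraction {sqrt, 0.5, 1.0} × min leaf {1, 5} (12); SVM
linear × cost {.1, 1, 10} plus RBF × cost {.1, 1, 10} × width
{scale, .1, 1} (12); KNN with k ∈ {3,5,7,9,11,15,21,31,41,51,75} (11) — 50
members, ids m1..m50, stable across calls. A 20-member `reduced_grid()`
with the same family mix serves smaller problems. All are **regressors on
the 0/1 outcome**: the continuous predictions are the stacking features and
need not lie in [0, 1]. Binary pair features are passed unscaled
(standardizing a {0,1} column is an affine map the linear/kernel families
absorb). KNN's k is capped at the training-fold size so small folds remain
valid.

Out-of-fold predictions come from a stratified (by response) seeded 10-fold
split; cancer type is not used for stratification. A leakage audit in the
tests retrains selected learners without a fold and reproduces the stored
OOF block exactly.

## GA ensemble selection and the stacked meta-model

A chromosome is a binary membership vector over the grid. Fitness is the
mean held-out AUC over 5 inner stratified folds of a stepwise-logistic
stack fitted on the chromosome's OOF columns — not the training AUC, which
is monotone in chromosome size under stepwise fitting and would collapse
the search toward the full ensemble (training-AUC fitness remains available
for fidelity experiments). Generation 0 seeds the all-ones chromosome and
the five best single-learner chromosomes by individual OOF AUC; the rest is
random with set-bit probability 0.3. Tournament selection (size 3),
single-point crossover (0.8), per-bit mutation (1/n_bits), elitism 2, and a
best-ever patience of 10 generations. Because the seeded individuals are in
generation 0 and fitness values are memoized, the returned chromosome never
scores below the all-ones stack or the best singleton, and the best-fitness
trace is non-decreasing — both asserted in the tests.

The meta-model is bidirectional stepwise logistic regression by AIC from
the intercept-only model (adds evaluated before drops, ties toward the
smaller column index); duplicated columns cannot both enter because the
second copy worsens AIC. The deployment score for a sample is the negated
linear predictor of the stack applied to **full-data** base-learner
predictions (standard stacked-generalization deployment), while the
meta-coefficients themselves are learned on OOF columns. Lower score =
more likely responder, always.

## Threshold and evaluation

The classification threshold maximizes Youden's J = TPR + TNR − 1 over
midpoints of consecutive sorted unique training scores (±∞ sentinels, ties
toward the smallest candidate), with "predicted responder" = score strictly
below the threshold. When all scores are equal, J = 0 everywhere and the
−∞ sentinel is returned (everyone predicted non-responder). The threshold
is learned on deployment-path training scores and frozen into the model
bundle so that it lives on the same scale `predict` emits. AUC uses the
Mann–Whitney tie-aware form; survival comparison between score groups uses
Kaplan–Meier curves and the two-group log-rank test via lifelines, with a
hand-computed hypergeometric fixture as the test oracle.

## Synthetic cohorts

The generator emulates exactly the structure the method consumes: cancer
type drawn from configured proportions; response Bernoulli with
type-specific rates (defaults: melanoma 0.40/30%, RCC 0.30/25%, NSCLC
0.20/25%, UC 0.15/20% — ICB monotherapy ORR ranges); K planted pairs on 2K
reserved disjoint genes whose orientation bit is Bernoulli(pi1) in
responders and Bernoulli(pi0) otherwise, realized with a strictly positive
gap |N(0, σ)| + 0.1 above a log-normal base value; all other genes i.i.d.
log-normal; a per-sample strictly increasing batch distortion applied last
(affine x → ax + b with a ∈ [0.5, 2], b ∈ [0, 1], or power x → x^γ with
γ ∈ [0.5, 2] on the strictly positive values); exponential survival with
baseline rate 0.03/month, responder hazard ratio 0.5 and uniform censoring
over 60 months. Everything is reproducible from a single seed.

Reference study conditions (the generator defaults): n = 600 training
samples, 60 genes, K = 5, pi1 = 0.9 / pi0 = 0.1, four cancer types. The
generator does **not** model RNA-seq count noise (library size, negative
binomial dispersion) or gene–gene correlation beyond the planted pairs;
passing tests therefore demonstrate the pipeline's mechanics, invariances
and recovery behavior under its own assumptions, not clinical performance
on real cohorts — where signals are far weaker and correlated.

## Problem sizes used by the test and acceptance runs

End-to-end checks run at the reference conditions above with the 20-member
reduced grid, a GA of population 16 / ≤ 8 generations / patience 4, and
held-out cohorts of 200 (planted runs) or 400 samples (null calibration,
where the wider held-out set makes the chance band [0.40, 0.60] a ≈3σ
interval per seed). The planted signal is strong enough that the shortened
GA reaches the same ensembles longer runs do; the GA's own contract
(monotone trace, dominance over its seeded individuals, bit-identical
reruns) is tested separately at full generality.

## Degenerate inputs and numerical choices

- Linear predictors are clipped at ±30 and IRLS weights floored at 1e-10;
  NLL uses `logaddexp` throughout.
- If screening passes zero pairs (expected under a pure-noise cohort), the
  pipeline carries forward the `min(20, p)` smallest-p pairs so downstream
  stages stay defined; held-out performance then hovers at chance. If the
  IC chooses the empty support, the single best pair by marginal score is
  kept.
- If the Youden threshold is not finite (all training scores equal), the
  bundle stores the median training score instead.
- Model bundles are a human-readable `manifest.json` (pairs, grid, stacked
  coefficients, threshold, orientation, seed) plus one joblib artifact per
  grid learner — forest/kernel learners have no compact plain-text form.
  Loading validates the format version and every artifact's presence;
  reloaded bundles score bit-identically.

## Known limitations

- Screening treats pairs independently; heavily overlapping pairs (shared
  genes) pass or fail together and the subset stage is the only place
  redundancy is resolved.
- The AUC gate is one-sided in orientation: a pair whose indicator is
  *negatively* associated with response (AUC < 0.4) fails the gate even
  though its reversed pair would pass; the enumeration covers both orders
  only through the gene-list order.
- Stepwise/AIC stacking with strongly separated OOF columns can retain a
  single learner; that is correct behavior under AIC but means the
  "ensemble" may be small when the signal is strong.
- The GA's fitness landscape is evaluated on OOF predictions from one
  10-fold split; a different outer split perturbs member choice (not,
  in the tested regimes, held-out performance).
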