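"""Base-learner grid and out-of-fold (stacking) predictions.

Fifty regression learners across four families — Elastic Net, Random
Forest, Support Vector Machine and K-Nearest Neighbors — are trained on
the binary pair features against the 0/1 response *as regressors*: their
continuous predictions, collected out-of-fold over a stratified 10-fold
split, form the feature space of the stacked meta-model. The grid is fixed
and documented (ENET 15, RF 12, SVM 12, KNN 11) but overridable; a reduced
20-member grid with the same family mix is provided for smaller problems.

Binary features are passed unscaled: standardization of a {0,1} column is
an affine map, which Elastic Net and SVR absorb into their coefficients and
which tree/neighbor models ignore up to the metric scale shared by all
columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR

FAMILIES = ("ENET", "RF", "SVM", "KNN")


@dataclass(frozen=True)
class LearnerConfig:
    id: str
    family: str
    hyperparameters: dict = field(hash=False)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown learner family {self.family!r}")


@dataclass
class OOFMatrix:
    """Out-of-fold predictions: samples x learners, plus the fold map."""

    values: np.ndarray
    fold_assignment: np.ndarray  # fold index per sample, 0..k-1
    learner_ids: list[str]

    def __post_init__(self) -> None:
        if self.values.shape != (self.fold_assignment.size, len(self.learner_ids)):
            raise ValueError("OOF matrix shape inconsistent")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("OOF predictions contain non-finite values")


def default_grid() -> list[LearnerConfig]:
    """The fixed 50-member grid, ids m1..m50 in deterministic order."""
    configs: list[LearnerConfig] = []
    for mixing in (0.0, 0.25, 0.5, 0.75, 1.0):
        for strength in (0.01, 0.1, 1.0):
            configs.append(_cfg("ENET", {"l1_ratio": mixing, "alpha": strength}, configs))
    for n_trees in (100, 500):
        for max_features in ("sqrt", 0.5, 1.0):
            for min_leaf in (1, 5):
                configs.append(
                    _cfg(
                        "RF",
                        {
                            "n_estimators": n_trees,
                            "max_features": max_features,
                            "min_samples_leaf": min_leaf,
                        },
                        configs,
                    )
                )
    for cost in (0.1, 1.0, 10.0):
        configs.append(_cfg("SVM", {"kernel": "linear", "C": cost}, configs))
    for cost in (0.1, 1.0, 10.0):
        for gamma in ("scale", 0.1, 1.0):
            configs.append(_cfg("SVM", {"kernel": "rbf", "C": cost, "gamma": gamma}, configs))
    for k in (3, 5, 7, 9, 11, 15, 21, 31, 41, 51, 75):
        configs.append(_cfg("KNN", {"n_neighbors": k}, configs))
    assert len(configs) == 50
    return configs


def reduced_grid() -> list[LearnerConfig]:
    """A 20-member grid with the same family mix, for smaller problems."""
    configs: list[LearnerConfig] = []
    for mixing in (0.0, 0.5, 1.0):
        for strength in (0.1, 1.0):
            configs.append(_cfg("ENET", {"l1_ratio": mixing, "alpha": strength}, configs))
    for max_features in ("sqrt", 1.0):
        for min_leaf in (1, 5):
            configs.append(
                _cfg(
                    "RF",
                    {"n_estimators": 100, "max_features": max_features, "min_samples_leaf": min_leaf},
                    configs,
                )
            )
    for cost in (0.1, 1.0, 10.0):
        configs.append(_cfg("SVM", {"kernel": "linear", "C": cost}, configs))
    for cost in (0.1, 1.0, 10.0):
        configs.append(_cfg("SVM", {"kernel": "rbf", "C": cost, "gamma": "scale"}, configs))
    for k in (5, 11, 21, 41):
        configs.append(_cfg("KNN", {"n_neighbors": k}, configs))
    assert len(configs) == 20
    return configs


def _cfg(family: str, params: dict, existing: list[LearnerConfig]) -> LearnerConfig:
    return LearnerConfig(id=f"m{len(existing) + 1}", family=family, hyperparameters=params)


def make_estimator(config: LearnerConfig, n_train: int, seed: int = 0):
    """Instantiate the sklearn regressor for one grid member.

    KNN's k is capped at the training-set size so small folds stay valid.
    """
    hp = config.hyperparameters
    if config.family == "ENET":
        return ElasticNet(alpha=hp["alpha"], l1_ratio=hp["l1_ratio"], max_iter=5000)
    if config.family == "RF":
        return RandomForestRegressor(
            n_estimators=hp["n_estimators"],
            max_features=hp["max_features"],
            min_samples_leaf=hp["min_samples_leaf"],
            random_state=seed,
            n_jobs=1,
        )
    if config.family == "SVM":
        kwargs = {"kernel": hp["kernel"], "C": hp["C"]}
        if hp["kernel"] == "rbf":
            kwargs["gamma"] = hp["gamma"]
        return SVR(**kwargs)
    if config.family == "KNN":
        return KNeighborsRegressor(n_neighbors=min(hp["n_neighbors"], n_train))
    raise ValueError(config.family)


def _fit(est, X: np.ndarray, y: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def fit_oof(
    F_sel: np.ndarray,
    y: np.ndarray,
    grid: list[LearnerConfig] | None = None,
    k: int = 10,
    seed: int = 0,
) -> tuple[OOFMatrix, dict]:
    """Stratified k-fold out-of-fold predictions plus full-data fits.

    Every learner's OOF column j for a sample comes from a model trained
    without that sample's fold; the returned ``full_fits`` (id -> fitted
    estimator) are the deployment models trained on all samples.
    """
    F_sel = np.asarray(F_sel, dtype=float)
    y = np.asarray(y, dtype=int)
    if grid is None:
        grid = default_grid()
    n = y.size
    if F_sel.shape[0] != n:
        raise ValueError("F_sel rows must align with y")
    if n < 2 * k:
        raise ValueError(f"need n >= 2k samples for {k}-fold CV, got n={n}")
    ids = [c.id for c in grid]
    if len(set(ids)) != len(ids):
        raise ValueError("learner ids must be unique")

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_assignment = np.empty(n, dtype=int)
    oof = np.full((n, len(grid)), np.nan)
    for fold, (train_idx, test_idx) in enumerate(skf.split(F_sel, y)):
        fold_assignment[test_idx] = fold
        y_tr = y[train_idx]
        if len(np.unique(y_tr)) < 2:
            raise ValueError(f"fold {fold}: training outcome has a single class")
        for j, cfg in enumerate(grid):
            est = make_estimator(cfg, n_train=train_idx.size, seed=seed + 1000 * j)
            _fit(est, F_sel[train_idx], y_tr.astype(float))
            oof[test_idx, j] = est.predict(F_sel[test_idx])
    if np.isnan(oof).any():
        raise RuntimeError("out-of-fold matrix has unfilled entries")

    full_fits = {}
    for j, cfg in enumerate(grid):
        est = make_estimator(cfg, n_train=n, seed=seed + 1000 * j)
        full_fits[cfg.id] = _fit(est, F_sel, y.astype(float))
    return OOFMatrix(values=oof, fold_assignment=fold_assignment, learner_ids=ids), full_fits


def predict_base(full_fits: dict, grid: list[LearnerConfig], F_new: np.ndarray) -> np.ndarray:
    """Predictions of every full-data learner on new samples (samples x learners)."""
    F_new = np.asarray(F_new, dtype=float)
    if F_new.ndim != 2:
        raise ValueError("F_new must be 2-D (samples x selected pairs)")
    cols = []
    for cfg in grid:
        est = full_fits[cfg.id]
        expected = getattr(est, "n_features_in_", F_new.shape[1])
        if F_new.shape[1] != expected:
            raise ValueError(
                f"feature mismatch for {cfg.id}: model expects {expected} "
                f"columns, got {F_new.shape[1]}"
            )
        cols.append(est.predict(F_new))
    out = np.column_stack(cols)
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite base-learner prediction")
    return out
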