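"""Per-pair screening: cancer-type-adjusted logistic regression + single-feature AUC.

Each candidate pair feature x is screened with the model

    logit P(y = 1) = b0 + b1 * x + sum_c gamma_c * 1[cancer_type = c]

(reference level = first type in sorted order) and kept when the two-sided
Wald p-value for b1 falls below ``p_thresh`` AND the feature's standalone
AUC for the response exceeds ``auc_thresh`` (both strict). Complete
separation — common for near-perfect binary features — triggers a
Jeffreys-prior (Firth) penalized refit, flagged ``separation_fallback``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._logistic import LogisticFit, fit_firth, fit_irls
from .pairs import PairFeatureMatrix

FLAG_OK = "ok"
FLAG_SEPARATION = "separation_fallback"
FLAG_FAILED = "fit_failed"

_SEPARATION_BETA = 10.0


def _design(cancer_type: list[str] | np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded cancer-type dummies (first sorted level = ref)."""
    ct = np.asarray(cancer_type, dtype=object)
    levels = sorted(set(ct.tolist()))
    n = ct.size
    cols = [np.ones(n)]
    for lev in levels[1:]:
        cols.append((ct == lev).astype(float))
    return np.column_stack(cols), levels


def fit_logistic_adjusted(
    x: np.ndarray,
    y: np.ndarray,
    cancer_type: list[str] | np.ndarray,
) -> tuple[float, float, float, str]:
    """Adjusted logistic fit for one feature.

    Returns (coefficient, standard error, two-sided Wald p, flag). The
    feature coefficient is on the log-odds scale. Separation (|b1| > 10 or
    non-convergence within 100 IRLS iterations) falls back to the Firth fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.size == 0:
        raise ValueError("empty input")
    if x.shape != y.shape or len(cancer_type) != x.size:
        raise ValueError("x, y and cancer_type must have equal lengths")
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class")
    if np.ptp(x) == 0:
        return np.nan, np.nan, np.nan, FLAG_FAILED
    base, _ = _design(cancer_type)
    X = np.column_stack([base[:, :1], x, base[:, 1:]])  # b1 is column 1
    fit: LogisticFit = fit_irls(X, y, max_iter=100)
    flag = FLAG_OK
    if not fit.converged or abs(fit.beta[1]) > _SEPARATION_BETA:
        fit = fit_firth(X, y)
        flag = FLAG_SEPARATION
        if not np.all(np.isfinite(fit.beta)):
            return np.nan, np.nan, np.nan, FLAG_FAILED
    return float(fit.beta[1]), float(fit.se[1]), fit.wald_p(1), flag


def pair_auc(x: np.ndarray, y: np.ndarray) -> float:
    """AUC of x for the positive class, with ties counting one half.

    Equals [#(x_pos > x_neg) + 0.5 * #(x_pos = x_neg)] / (n_pos * n_neg)
    over all positive-negative sample pairs (the Mann-Whitney statistic),
    computed via average ranks.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=int)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal lengths")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("response has a single class")
    r = rankdata(x)  # average ranks handle ties exactly
    rank_sum_pos = float(np.sum(r[y == 1]))
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)


def screen_pairs(
    F: PairFeatureMatrix,
    y: np.ndarray,
    cancer_type: list[str] | np.ndarray,
    p_thresh: float = 0.001,
    auc_thresh: float = 0.6,
) -> pd.DataFrame:
    """Screen every pair; returns one row per pair.

    Columns: gene_a, gene_b, coefficient, p_value, auc, flag, pass. A pair
    passes iff p_value < p_thresh AND auc > auc_thresh (strict) and the fit
    did not fail; constant pairs auto-fail with ``fit_failed``. No multiple-
    testing correction is applied: the gate is a raw p-value threshold.
    """
    if not (0.0 < p_thresh < 1.0 and 0.0 < auc_thresh < 1.0):
        raise ValueError("thresholds must lie in (0,1)")
    y = np.asarray(y, dtype=int)
    rows = []
    for i, pair in enumerate(F.pairs):
        x = F.values[i].astype(float)
        if np.ptp(x) == 0:
            rows.append((pair.gene_a, pair.gene_b, np.nan, np.nan, np.nan, FLAG_FAILED, False))
            continue
        coef, _se, p, flag = fit_logistic_adjusted(x, y, cancer_type)
        if flag == FLAG_FAILED:
            rows.append((pair.gene_a, pair.gene_b, coef, p, np.nan, flag, False))
            continue
        auc = pair_auc(x, y)
        ok = bool(p < p_thresh and auc > auc_thresh)
        rows.append((pair.gene_a, pair.gene_b, coef, p, auc, flag, ok))
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "coefficient", "p_value", "auc", "flag", "pass"],
    )
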