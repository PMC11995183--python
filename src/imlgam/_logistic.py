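"""Lean logistic-regression fitting used across screening, subset search and stacking.

A hand-rolled Newton/IRLS solver is used instead of a general GLM framework
because the pipeline performs on the order of 10^4-10^6 small fits (one per
candidate gene pair, per splicing exchange, per stepwise move); the designs
are tiny (<= ~15 columns) so a dense solve per iteration is the fast path.
A Jeffreys-prior (Firth) penalized variant guards against complete
separation, which binary pair features readily produce.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

_ETA_CLIP = 30.0  # linear predictor bound; keeps weights/probabilities finite
_W_FLOOR = 1e-10


@dataclass
class LogisticFit:
    """Result of a (possibly penalized) logistic fit.

    beta includes the intercept as the first coefficient when the design
    carries an intercept column (the callers always prepend one).
    """

    beta: np.ndarray
    se: np.ndarray
    nll: float
    converged: bool
    n_iter: int
    penalized: bool = False

    def wald_p(self, j: int) -> float:
        """Two-sided Wald p-value for coefficient j."""
        if not np.isfinite(self.se[j]) or self.se[j] <= 0:
            return 1.0
        z = self.beta[j] / self.se[j]
        return float(2.0 * norm.sf(abs(z)))


def _nll(eta: np.ndarray, y: np.ndarray) -> float:
    # sum log(1 + exp(eta)) - y*eta, computed stably
    return float(np.sum(np.logaddexp(0.0, eta) - y * eta))


def fit_irls(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    X must already contain any intercept column. Non-convergence is reported,
    not raised: under separation the likelihood has no finite maximizer and
    the caller decides whether to fall back to the penalized fit.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = np.maximum(p * (1.0 - p), _W_FLOOR)
        Xw = X * w[:, None]
        H = X.T @ Xw
        g = X.T @ (y - p)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(k), g)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    p = expit(eta)
    w = np.maximum(p * (1.0 - p), _W_FLOOR)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    return LogisticFit(beta=beta, se=se, nll=_nll(eta, y), converged=converged, n_iter=it)


def fit_firth(
    X: np.ndarray,
    y: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> LogisticFit:
    """Firth-penalized logistic fit (Jeffreys prior on the coefficients).

    The modified score is U*(b) = X'(y - p + h (1/2 - p)) with h the hat
    diagonal; the penalized estimate is finite even under complete
    separation. Standard errors come from the observed information.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = np.maximum(p * (1.0 - p), _W_FLOOR)
        Xw = X * w[:, None]
        H = X.T @ Xw
        try:
            Hinv = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            Hinv = np.linalg.inv(H + 1e-8 * np.eye(k))
        # hat diagonal: h_i = w_i * x_i' H^{-1} x_i
        h = w * np.einsum("ij,jk,ik->i", X, Hinv, X)
        U = X.T @ (y - p + h * (0.5 - p))
        step = Hinv @ U
        # damped update keeps the penalized iteration stable on small n
        snorm = np.max(np.abs(step))
        if snorm > 5.0:
            step = step * (5.0 / snorm)
        beta = beta + step
        if np.max(np.abs(U)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
    p = expit(eta)
    w = np.maximum(p * (1.0 - p), _W_FLOOR)
    H = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    sign, logdet = np.linalg.slogdet(H)
    pen_nll = _nll(eta, y) - 0.5 * (logdet if sign > 0 else -np.inf)
    return LogisticFit(
        beta=beta, se=se, nll=pen_nll, converged=converged, n_iter=it, penalized=True
    )


def logistic_nll(X: np.ndarray, y: np.ndarray, max_iter: int = 50) -> tuple[np.ndarray, float]:
    """Fit and return (beta, NLL); convenience for subset search and stacking."""
    fit = fit_irls(X, y, max_iter=max_iter)
    return fit.beta, fit.nll


def intercept_only_nll(y: np.ndarray) -> float:
    """Closed-form NLL of the intercept-only model (null deviance / 2)."""
    y = np.asarray(y, dtype=float)
    n = y.size
    n1 = float(y.sum())
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return 0.0
    p = n1 / n
    return float(-(n1 * np.log(p) + n0 * np.log(1.0 - p)))
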