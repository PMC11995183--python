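"""Adaptive best-subset selection for the logistic outcome via splicing.

The search approximates, for each support size s, the L0-constrained
maximum-likelihood support: start from the s features with the largest
marginal score statistics, then repeatedly *splice* — exchange up to k_max
features between the active and inactive sets, ranked by how little they
contribute (active) and how much they would contribute (inactive) — and
accept an exchange when it lowers the negative log-likelihood by more than
tau. Support size is then tuned by a high-dimensional information criterion

    IC(s) = 2 * NLL(s) + s * log(p) * log(log(max(n, 3)))

with ties broken toward smaller s. The whole stage is deterministic:
initialization is by marginal ranking, no randomness enters.

``exhaustive_best_subset`` is a brute-force enumerator kept as the testing
oracle for the splicing search; it is never used by the pipeline itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.special import expit

from ._logistic import fit_irls, intercept_only_nll


@dataclass
class SubsetSelection:
    selected_pairs: list[int]  # column indices into F
    support_size: int
    ic_path: dict[int, tuple[float, float]]  # s -> (NLL, IC)
    s_max: int


def _check_inputs(F: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=int)
    if F.ndim != 2 or F.shape[0] != y.size:
        raise ValueError("F must be samples x features aligned with y")
    if len(np.unique(y)) < 2:
        raise ValueError("response has a single class")
    return F, y


def _fit_support(
    F: np.ndarray, y: np.ndarray, support: tuple[int, ...]
) -> tuple[float, np.ndarray, float]:
    """Logistic fit restricted to `support`; returns (intercept, full beta, NLL)."""
    n, p = F.shape
    if not support:
        ybar = float(np.mean(y))
        b0 = np.log(ybar / (1 - ybar)) if 0 < ybar < 1 else 0.0
        return b0, np.zeros(p), intercept_only_nll(y)
    X = np.column_stack([np.ones(n), F[:, list(support)]])
    fit = fit_irls(X, y, max_iter=60)
    beta = np.zeros(p)
    beta[list(support)] = fit.beta[1:]
    return float(fit.beta[0]), beta, fit.nll


def marginal_scores(F: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Absolute standardized score statistic of each feature for the response."""
    F = np.asarray(F, dtype=float)
    y = np.asarray(y, dtype=float)
    ybar = y.mean()
    resid = y - ybar
    num = np.abs(F.T @ resid)
    centered = F - F.mean(axis=0, keepdims=True)
    denom = np.sqrt(ybar * (1 - ybar) * np.sum(centered**2, axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, num / denom, 0.0)
    return z


def splicing_best_subset(
    F: np.ndarray,
    y: np.ndarray,
    s: int,
    k_max: int | None = None,
    tau: float = 1e-6,
    max_sweeps: int = 20,
) -> tuple[list[int], float]:
    """Approximate the size-s support minimizing the logistic NLL.

    Exchanges are ranked by *sacrifices*: for an active feature j the loss
    incurred by dropping it, xi_j = b_j^2 * (x_j' W x_j) / 2; for an
    inactive feature the gain from adding it, zeta_j = d_j^2 *
    (x_j' W x_j) / 2 with d_j the weighted-score step. W and the residual
    come from the current active-set fit.
    """
    F, y = _check_inputs(F, y)
    n, p = F.shape
    if not 1 <= s <= p:
        raise ValueError(f"support size {s} out of range [1, {p}]")
    if s > max(1, n // 4):
        raise ValueError(f"support size {s} too large for n={n} (limit n/4)")
    if k_max is None:
        k_max = min(s, 5)

    order = np.argsort(-marginal_scores(F, y), kind="stable")
    active = sorted(order[:s].tolist())
    b0, beta, nll = _fit_support(F, y, tuple(active))

    if s == p:
        return active, nll

    for _ in range(max_sweeps):
        improved = False
        active_arr = np.array(active, dtype=int)
        inactive_arr = np.array(sorted(set(range(p)) - set(active)), dtype=int)
        eta = F[:, active_arr] @ beta[active_arr] + b0
        prob = expit(np.clip(eta, -30, 30))
        w = np.maximum(prob * (1 - prob), 1e-10)
        resid = y - prob
        xtwx = np.einsum("ij,i,ij->j", F, w, F)
        # backward sacrifice (active): cost of zeroing the coefficient
        xi = 0.5 * beta[active_arr] ** 2 * xtwx[active_arr]
        # forward sacrifice (inactive): gain from a one-step update
        d = (F[:, inactive_arr].T @ resid) / np.maximum(xtwx[inactive_arr], 1e-12)
        zeta = 0.5 * d**2 * xtwx[inactive_arr]
        drop_order = active_arr[np.argsort(xi, kind="stable")]
        add_order = inactive_arr[np.argsort(-zeta, kind="stable")]
        for k in range(1, min(k_max, inactive_arr.size, s) + 1):
            cand = sorted(
                (set(active) - set(drop_order[:k].tolist())) | set(add_order[:k].tolist())
            )
            cand_b0, cand_beta, cand_nll = _fit_support(F, y, tuple(cand))
            if cand_nll < nll - tau:
                active, b0, beta, nll = cand, cand_b0, cand_beta, cand_nll
                improved = True
                break
        if not improved:
            # ranked block exchange exhausted: refine with single-coordinate
            # swaps (least-useful actives x most-promising inactives), taking
            # the best improving exchange if any
            n_in = min(inactive_arr.size, 20)
            best: tuple[float, list[int]] | None = None
            for j_out in drop_order[: min(s, 5)]:
                for j_in in add_order[:n_in]:
                    cand = sorted((set(active) - {int(j_out)}) | {int(j_in)})
                    _, _, cand_nll = _fit_support(F, y, tuple(cand))
                    if cand_nll < nll - tau and (best is None or cand_nll < best[0]):
                        best = (cand_nll, cand)
            if best is not None:
                active = best[1]
                b0, beta, nll = _fit_support(F, y, tuple(active))
                improved = True
        if not improved:
            break
    return sorted(active), nll


def exhaustive_best_subset(
    F: np.ndarray, y: np.ndarray, s: int, budget: int = 100_000
) -> tuple[list[int], float]:
    """Exact size-s minimizer by enumeration (testing oracle only).

    Ties are broken toward the lexicographically smallest support.
    """
    F, y = _check_inputs(F, y)
    p = F.shape[1]
    if s == 0:
        return [], intercept_only_nll(y)
    if not 1 <= s <= p:
        raise ValueError(f"support size {s} out of range [0, {p}]")
    from math import comb

    if comb(p, s) > budget:
        raise ValueError(f"C({p},{s}) exceeds the enumeration budget {budget}")
    best_support: tuple[int, ...] | None = None
    best_nll = np.inf
    for support in combinations(range(p), s):
        _, _, nll = _fit_support(F, y, support)
        if nll < best_nll - 1e-12:
            best_support, best_nll = support, nll
    assert best_support is not None
    return list(best_support), best_nll


def select_support_size(
    F: np.ndarray,
    y: np.ndarray,
    s_max: int,
    k_max: int | None = None,
    tau: float = 1e-6,
) -> SubsetSelection:
    """Run splicing for s = 0..s_max and pick the IC-minimizing support."""
    F, y = _check_inputs(F, y)
    n, p = F.shape
    if s_max < 0:
        raise ValueError("s_max must be >= 0")
    s_cap = min(s_max, p, max(1, n // 4))
    penalty_unit = np.log(max(p, 2)) * np.log(np.log(max(n, 3)))
    ic_path: dict[int, tuple[float, float]] = {}
    supports: dict[int, list[int]] = {0: []}
    nll0 = intercept_only_nll(y)
    ic_path[0] = (nll0, 2 * nll0)
    for s in range(1, s_cap + 1):
        support, nll = splicing_best_subset(F, y, s, k_max=k_max, tau=tau)
        # enforce monotone NLL along the path: a larger support can never fit
        # worse than a smaller one; fall back to the nested extension if the
        # heuristic search landed higher
        prev_nll = ic_path[s - 1][0]
        if nll > prev_nll + 1e-8 and s > 1:
            prev_support = supports[s - 1]
            rest = [j for j in range(p) if j not in prev_support]
            if rest:
                scores = marginal_scores(F, y)
                extra = max(rest, key=lambda j: scores[j])
                cand = sorted(prev_support + [extra])
                _, _, cand_nll = _fit_support(F, y, tuple(cand))
                if cand_nll < nll:
                    support, nll = cand, cand_nll
        supports[s] = support
        ic_path[s] = (nll, 2 * nll + s * penalty_unit)
    best_s = min(ic_path, key=lambda s: (ic_path[s][1], s))
    return SubsetSelection(
        selected_pairs=supports[best_s],
        support_size=best_s,
        ic_path=ic_path,
        s_max=s_cap,
    )
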