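"""Gene-pair enumeration and the binary relative-ordering feature matrix.

The feature for pair (a, b) in sample s is 1 iff expression of a strictly
exceeds expression of b within that sample (ties score 0). Because only
within-sample orderings enter, the features are exactly invariant to any
per-sample strictly increasing transform — the property that makes the
score portable across platforms and batches without explicit correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .data_io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePair:
    """An ordered gene pair; gene_a precedes gene_b in the supplied list order."""

    gene_a: str
    gene_b: str

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"pair genes must differ, got {self.gene_a!r} twice")

    @property
    def name(self) -> str:
        return f"{self.gene_a}|{self.gene_b}"


@dataclass
class PairFeatureMatrix:
    """Binary pairs x samples indicator matrix."""

    pairs: list[GenePair]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_pairs, n_samples), uint8 in {0,1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.pairs), len(self.sample_ids)):
            raise ValueError("feature matrix shape inconsistent with pairs/samples")
        uniq = np.unique(self.values)
        if not set(uniq.tolist()) <= {0, 1}:
            raise ValueError("pair features must be binary")
        self.values = self.values.astype(np.uint8)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def samples_by_pairs(self) -> np.ndarray:
        """Feature matrix as samples x pairs float array (model input layout)."""
        return self.values.T.astype(float)


def enumerate_pairs(gene_list: list[str], expr: ExpressionMatrix) -> list[GenePair]:
    """All unordered pairs of listed genes present in the expression matrix.

    Order follows list positions: (a, b) with a earlier than b, pairs sorted
    by (position of a, position of b). Listed genes missing from the matrix
    are dropped with a logged count.
    """
    if not gene_list:
        raise ValueError("gene list is empty")
    present_set = set(expr.gene_ids)
    usable = [g for g in gene_list if g in present_set]
    dropped = [g for g in gene_list if g not in present_set]
    if dropped:
        logger.info(
            "dropping %d listed genes absent from expression (e.g. %s)",
            len(dropped),
            dropped[:5],
        )
    if len(usable) < 2:
        raise ValueError(
            f"need at least 2 listed genes present in expression, found {len(usable)}"
        )
    return [
        GenePair(usable[i], usable[j])
        for i in range(len(usable))
        for j in range(i + 1, len(usable))
    ]


def pair_features(expr: ExpressionMatrix, pairs: list[GenePair]) -> PairFeatureMatrix:
    """Indicator matrix: value(p, s) = 1 iff expr[gene_a, s] > expr[gene_b, s]."""
    gidx = expr.gene_index()
    missing = sorted(
        {g for p in pairs for g in (p.gene_a, p.gene_b) if g not in gidx}
    )
    if missing:
        raise KeyError(f"pair genes absent from expression matrix: {missing[:5]}")
    ia = np.array([gidx[p.gene_a] for p in pairs], dtype=int)
    ib = np.array([gidx[p.gene_b] for p in pairs], dtype=int)
    values = (expr.values[ia, :] > expr.values[ib, :]).astype(np.uint8)
    return PairFeatureMatrix(pairs=list(pairs), sample_ids=list(expr.sample_ids), values=values)


def drop_degenerate(F: PairFeatureMatrix, min_frac: float = 0.0) -> PairFeatureMatrix:
    """Remove near-constant pairs: mean indicator < min_frac or > 1 - min_frac.

    The default min_frac = 0 removes only strictly constant pairs. This is a
    pragmatic pre-filter (constant features carry no ordering information and
    break downstream fits); it is not part of the screening statistics.
    """
    if not 0.0 <= min_frac < 0.5:
        raise ValueError("min_frac must lie in [0, 0.5)")
    means = F.values.mean(axis=1)
    if min_frac == 0.0:
        keep = (means > 0.0) & (means < 1.0)
    else:
        keep = (means >= min_frac) & (means <= 1.0 - min_frac)
    idx = np.flatnonzero(keep)
    return PairFeatureMatrix(
        pairs=[F.pairs[i] for i in idx],
        sample_ids=list(F.sample_ids),
        values=F.values[idx, :],
    )
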