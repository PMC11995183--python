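"""Synthetic ICB-like cohort generator.

Emulates the structure the scoring pipeline consumes: a binary treatment
response with cancer-type-specific base rates, a small set of planted gene
pairs whose within-sample ordering carries the response signal, per-sample
strictly monotone batch distortions (which the pair features must be blind
to), and exponential overall survival with a responder hazard ratio.

It deliberately does not model RNA-seq count noise (library size, negative
binomial dispersion): only within-sample orderings reach the method, so the
rank structure — not the marginal noise law — is what matters for testing.

Default configuration
---------------------
The defaults describe a mid-sized pan-cancer ICB cohort: n = 600 samples,
60 immune genes, K = 5 planted pairs with orientation probabilities
pi1 = 0.9 (responders) / pi0 = 0.1 (non-responders), four cancer types with
objective-response rates in the range reported for ICB monotherapy
(melanoma ~0.40 down to urothelial ~0.15), affine per-sample distortion,
and exponential survival with a responder hazard ratio of 0.5 and uniform
censoring over five years.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import ClinicalTable, ExpressionMatrix
from .pairs import GenePair

DEFAULT_CANCER_TYPES: list[tuple[str, float, float]] = [
    ("melanoma", 0.30, 0.40),
    ("RCC", 0.25, 0.30),
    ("NSCLC", 0.25, 0.20),
    ("UC", 0.20, 0.15),
]


@dataclass
class SurvivalConfig:
    enabled: bool = True
    baseline_rate: float = 0.03  # events per month for non-responders
    responder_hr: float = 0.5  # hazard ratio applied to responders
    censor_max: float = 60.0  # uniform censoring upper bound, months

    def validate(self) -> None:
        if self.enabled:
            if self.baseline_rate <= 0:
                raise ValueError("baseline_rate must be positive")
            if self.responder_hr <= 0:
                raise ValueError("responder_hr must be positive")
            if self.censor_max <= 0:
                raise ValueError("censor_max must be positive")


@dataclass
class SynthConfig:
    """Generator settings; defaults are the package's reference study conditions."""

    n_samples: int = 600
    n_genes: int = 60
    cancer_types: list[tuple[str, float, float]] = field(
        default_factory=lambda: list(DEFAULT_CANCER_TYPES)
    )
    planted_pairs: int = 5
    pi1: float = 0.9  # P(first gene > second | responder)
    pi0: float = 0.1  # P(first gene > second | non-responder)
    batch_distortion: str = "affine"  # none | affine | power
    affine_scale_range: tuple[float, float] = (0.5, 2.0)
    affine_shift_range: tuple[float, float] = (0.0, 1.0)
    power_range: tuple[float, float] = (0.5, 2.0)
    gap_sigma: float = 1.0  # planted-pair gap ~ |N(0, gap_sigma)| + gap_eps
    gap_eps: float = 0.1
    lognorm_mu: float = 2.0
    lognorm_sigma: float = 1.0
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1 or self.n_genes < 1:
            raise ValueError("n_samples and n_genes must be positive")
        if self.planted_pairs < 0:
            raise ValueError("planted_pairs must be >= 0")
        if 2 * self.planted_pairs > self.n_genes:
            raise ValueError(
                f"planted pairs need {2 * self.planted_pairs} reserved genes "
                f"but only {self.n_genes} are available"
            )
        props = [p for _, p, _ in self.cancer_types]
        if not self.cancer_types or abs(sum(props) - 1.0) > 1e-8:
            raise ValueError("cancer-type proportions must sum to 1")
        for name, p, rr in self.cancer_types:
            if not name:
                raise ValueError("cancer-type name must be non-empty")
            if p < 0:
                raise ValueError("cancer-type proportions must be non-negative")
            if not 0.0 < rr < 1.0:
                raise ValueError(f"responder rate for {name!r} must lie in (0,1)")
        if not (0.0 <= self.pi0 <= 1.0 and 0.0 <= self.pi1 <= 1.0):
            raise ValueError("pi0/pi1 must lie in [0,1]")
        if self.batch_distortion not in {"none", "affine", "power"}:
            raise ValueError("batch_distortion must be none, affine or power")
        if self.affine_scale_range[0] <= 0:
            raise ValueError("affine scale must be strictly positive")
        if self.power_range[0] <= 0:
            raise ValueError("power exponent must be strictly positive")
        self.survival.validate()


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests."""

    planted_pairs: list[GenePair]
    orientation: np.ndarray  # shape (K, n_samples), {0,1}
    pi1: float
    pi0: float
    seed: int


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix
    clinical: ClinicalTable
    truth: SyntheticTruth

    def split(self, n_train: int) -> tuple["SyntheticDataset", "SyntheticDataset"]:
        """Split by sample position into a training and a held-out cohort."""
        n = self.expression.n_samples
        if not 0 < n_train < n:
            raise ValueError(f"n_train must be in (0, {n})")

        def take(sl: slice) -> SyntheticDataset:
            sids = self.expression.sample_ids[sl]
            expr = ExpressionMatrix(
                gene_ids=list(self.expression.gene_ids),
                sample_ids=sids,
                values=self.expression.values[:, sl],
            )
            truth = SyntheticTruth(
                planted_pairs=list(self.truth.planted_pairs),
                orientation=self.truth.orientation[:, sl],
                pi1=self.truth.pi1,
                pi0=self.truth.pi0,
                seed=self.truth.seed,
            )
            return SyntheticDataset(expr, self.clinical.reorder(sids), truth)

        return take(slice(0, n_train)), take(slice(n_train, n))


def _gene_ids(n_genes: int) -> list[str]:
    width = max(3, len(str(n_genes)))
    return [f"IRG{i + 1:0{width}d}" for i in range(n_genes)]


def generate(config: SynthConfig) -> SyntheticDataset:
    """Draw one cohort; bit-identical for identical (config, seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, g, K = config.n_samples, config.n_genes, config.planted_pairs

    # cancer type and response
    names = [name for name, _, _ in config.cancer_types]
    props = np.array([p for _, p, _ in config.cancer_types])
    rates = {name: rr for name, _, rr in config.cancer_types}
    type_idx = rng.choice(len(names), size=n, p=props / props.sum())
    cancer_type = [names[i] for i in type_idx]
    response = np.array(
        [rng.random() < rates[c] for c in cancer_type], dtype=int
    )

    # baseline expression: i.i.d. log-normal everywhere
    values = rng.lognormal(config.lognorm_mu, config.lognorm_sigma, size=(g, n))

    # planted pairs on 2K reserved, disjoint genes: pair j = (gene 2j, gene 2j+1)
    gene_ids = _gene_ids(g)
    planted = [GenePair(gene_ids[2 * j], gene_ids[2 * j + 1]) for j in range(K)]
    orientation = np.zeros((K, n), dtype=np.uint8)
    for j in range(K):
        p_z = np.where(response == 1, config.pi1, config.pi0)
        z = (rng.random(n) < p_z).astype(np.uint8)
        orientation[j] = z
        base = rng.lognormal(config.lognorm_mu, config.lognorm_sigma, size=n)
        gap = np.abs(rng.normal(0.0, config.gap_sigma, size=n)) + config.gap_eps
        hi, lo = base + gap, base
        a_row, b_row = 2 * j, 2 * j + 1
        values[a_row] = np.where(z == 1, hi, lo)
        values[b_row] = np.where(z == 1, lo, hi)

    # per-sample strictly increasing distortion, applied last
    if config.batch_distortion == "affine":
        a = rng.uniform(*config.affine_scale_range, size=n)
        b = rng.uniform(*config.affine_shift_range, size=n)
        values = values * a[None, :] + b[None, :]
    elif config.batch_distortion == "power":
        gamma = rng.uniform(*config.power_range, size=n)
        values = values ** gamma[None, :]

    expr = ExpressionMatrix(gene_ids=gene_ids, sample_ids=[f"S{i + 1:04d}" for i in range(n)], values=values)

    os_time = os_event = None
    if config.survival.enabled:
        rate = config.survival.baseline_rate * np.power(
            config.survival.responder_hr, response
        )
        t = rng.exponential(1.0 / rate)
        c = rng.uniform(0.0, config.survival.censor_max, size=n)
        os_time = np.minimum(t, c)
        os_event = (t <= c).astype(int)

    clinical = ClinicalTable(
        sample_ids=list(expr.sample_ids),
        response=response,
        cancer_type=cancer_type,
        os_time=os_time,
        os_event=os_event,
    )
    truth = SyntheticTruth(
        planted_pairs=planted,
        orientation=orientation,
        pi1=config.pi1,
        pi0=config.pi0,
        seed=config.seed,
    )
    return SyntheticDataset(expression=expr, clinical=clinical, truth=truth)
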