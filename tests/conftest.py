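import numpy as np
import pytest

import imlgam as im
from imlgam.learners import LearnerConfig


def tiny_grid() -> list[LearnerConfig]:
    """A 4-member grid (one per family) for fast training in fixtures."""
    return [
        LearnerConfig(id="t1", family="ENET", hyperparameters={"l1_ratio": 0.5, "alpha": 0.1}),
        LearnerConfig(
            id="t2",
            family="RF",
            hyperparameters={"n_estimators": 50, "max_features": 1.0, "min_samples_leaf": 5},
        ),
        LearnerConfig(id="t3", family="SVM", hyperparameters={"kernel": "linear", "C": 1.0}),
        LearnerConfig(id="t4", family="KNN", hyperparameters={"n_neighbors": 11}),
    ]


@pytest.fixture(scope="session")
def planted_dataset() -> im.SyntheticDataset:
    """A strongly planted 300-sample cohort shared across read-only tests."""
    return im.generate(im.SynthConfig(n_samples=300, n_genes=40, seed=11))


@pytest.fixture(scope="session")
def trained_model(planted_dataset):
    """A small end-to-end model (tiny grid, short GA) for scoring/bundle tests."""
    ds = planted_dataset
    return im.train(
        ds.expression,
        ds.clinical,
        ds.expression.gene_ids,
        grid=tiny_grid(),
        k_folds=5,
        ga=im.GAConfig(population=10, generations=4, patience=2, seed=7),
        inner_k=3,
        seed=7,
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
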