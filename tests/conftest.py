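"""Shared fixtures: synthetic cohorts and small constructed datasets."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import bcsubtype as bc

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_cohort() -> bc.SimulatedCohort:
    """The default noisy study cohort (1000 genes, 350 samples, 5 classes)."""
    return bc.simulate_cohort(bc.SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def noiseless_cohort() -> bc.SimulatedCohort:
    """Small zero-noise cohort: every sample equals its class centroid."""
    config = bc.SimulationConfig(
        n_genes=200, n_informative=50, noise_sd=0.0, ambiguous_fraction=0.0,
        class_counts={"LUMA": 30, "LUMB": 25, "BASAL": 20, "HER2": 15, "NORMAL": 12},
        seed=11,
    )
    return bc.simulate_cohort(config)


@pytest.fixture(scope="session")
def toy_centroids() -> bc.CentroidTable:
    """5-gene, 2-class toy with mirror-image centroids."""
    return bc.CentroidTable(pd.DataFrame(
        {"A": [1.0, 2.0, 3.0, 4.0, 5.0], "B": [5.0, 4.0, 3.0, 2.0, 1.0]},
        index=["G1", "G2", "G3", "G4", "G5"],
    ))


@pytest.fixture(scope="session")
def bwe_fixture() -> tuple[bc.ExpressionMatrix, dict[str, str]]:
    """Two-gene cohort constructed so the pure-noise gene strictly degrades
    cross-validated accuracy: one clean informative gene, one high-variance
    noise gene, few samples (so the noise gene overfits)."""
    rng = np.random.default_rng(3)
    n = 24
    y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
    info = np.where(y == "A", -1.2, 1.2) + rng.normal(0, 1.0, n)
    noise = rng.normal(0, 3.0, n)
    samples = [f"S{i:02d}" for i in range(n)]
    expr = bc.ExpressionMatrix(
        pd.DataFrame([info, noise], index=["INFO", "NOISE"], columns=samples)
    )
    return expr, dict(zip(samples, y))


@pytest.fixture(scope="session")
def bwe_trainer():
    return bc.cv_accuracy_trainer(l1=0.01, l2=0.01, folds=4, seed=0)


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="mLR fit did not converge")
        yield
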