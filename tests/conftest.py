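"""Shared fixtures: baseline parameters, a ground-truth set, a synthetic
dataset and one desk-scale calibrated ensemble (session-scoped; the
calibration is the expensive step and several tests interrogate it)."""

import numpy as np
import pytest

from palmcycle import (
    PalmitoylationModel,
    baseline_parameters,
    generate_dataset,
    sample_ground_truth,
)

TRUTH_SEED = 2
FIT_SEED = 3


@pytest.fixture(scope="session")
def baseline():
    return baseline_parameters()


@pytest.fixture(scope="session")
def truth():
    return sample_ground_truth(seed=TRUTH_SEED)


@pytest.fixture(scope="session")
def dataset(truth):
    return generate_dataset(truth, seed=TRUTH_SEED)


@pytest.fixture(scope="session")
def fit_results(dataset):
    """Desk-scale ensemble calibration (population 200, 50 generations)."""
    model = PalmitoylationModel(dataset)
    return model.fit(population_size=200, generations=50, seed=FIT_SEED)


@pytest.fixture(scope="session")
def ensemble(fit_results):
    return fit_results.ensemble


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
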