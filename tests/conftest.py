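"""Shared fixtures: synthetic nuisance models and reusable DGM draws."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from mixshift.data import MixtureDataset, ShiftSpec
from mixshift.nuisance import OutcomeModel, RatioModel
from mixshift.simulation import SimScenario, simulate_dataset

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


class FuncEstimator:
    """sklearn-like regressor wrapping an arbitrary function of X=[W, A]."""

    def __init__(self, func):
        self.func = func

    def predict(self, X):
        return np.asarray(self.func(np.asarray(X)), dtype=float)


def make_outcome_model(func, y_lo=-10.0, y_hi=10.0, binary=False) -> OutcomeModel:
    """An OutcomeModel with a known closed-form regression function."""
    return OutcomeModel(
        estimator=FuncEstimator(func),
        learner_name="synthetic",
        cv_losses={},
        y_lo=y_lo,
        y_hi=y_hi,
        binary=binary,
    )


def unit_ratio_model(spec: ShiftSpec) -> RatioModel:
    """A direct-density RatioModel with no components: ratio identically 1."""
    return RatioModel(method="direct-density", spec=spec)


@pytest.fixture(scope="session")
def small_table() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "W1": [0.1, -0.3, 0.5],
            "W2": [1.0, 0.2, -0.7],
            "A1": [1.0, 2.0, 3.0],
            "A2": [0.5, 0.6, 0.7],
            "Y": [0.0, 1.0, 1.0],
        }
    )


@pytest.fixture(scope="session")
def gaussian_exposure_data() -> MixtureDataset:
    """One confounder (irrelevant), one standard-normal exposure, n=5000."""
    rng = np.random.default_rng(20240901)
    n = 5000
    W = rng.standard_normal((n, 1))
    A = rng.standard_normal((n, 1))
    Y = A[:, 0] + rng.standard_normal(n)
    return MixtureDataset(W=W, A=A, Y=Y, confounder_names=("W1",),
                          exposure_names=("A1",))


@pytest.fixture(scope="session")
def two_gaussian_exposures() -> MixtureDataset:
    """Two independent standard-normal exposures, n=5000."""
    rng = np.random.default_rng(77)
    n = 5000
    W = rng.standard_normal((n, 1))
    A = rng.standard_normal((n, 2))
    Y = A.sum(axis=1) + rng.standard_normal(n)
    return MixtureDataset(W=W, A=A, Y=Y, confounder_names=("W1",),
                          exposure_names=("A1", "A2"))


@pytest.fixture(scope="session")
def dgm_scenario_06() -> SimScenario:
    return SimScenario(n=2000, synergy=0.60, antagonism=-0.70, seed=11,
                       replicates=1)


@pytest.fixture(scope="session")
def dgm_draw_2000(dgm_scenario_06) -> MixtureDataset:
    """One n=2000 draw from the benchmark DGM at large synergy."""
    return simulate_dataset(dgm_scenario_06, seed=31415)
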