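import dataclasses
import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from prostate_dss.cohort import CohortSpec, generate_cohort
from prostate_dss.core import StageLabel, SystemConfig
from prostate_dss.pipeline import train_system

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    """A reduced but otherwise default-conditions cohort spec for unit tests."""
    return CohortSpec(n_per_class={s: 60 for s in StageLabel}, seed=3)


@pytest.fixture(scope="session")
def small_config() -> SystemConfig:
    # shorter MLP budget keeps unit tests quick; everything else is default
    return SystemConfig(seed=3, mlp_max_epochs=500)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def small_system(small_cohort, small_config):
    """One trained system shared by the unit tests that need a fitted model."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return train_system(small_cohort, small_config)


@pytest.fixture()
def clean_spec() -> CohortSpec:
    """Near-noise-free generator spec for separability-style checks."""
    return CohortSpec(
        n_per_class={s: 40 for s in StageLabel},
        severity_sd=0.05,
        noise_sd=0.01,
        seed=9,
    )


def make_blobs_6d(rng: np.random.Generator, centers: np.ndarray, n_per: int, sd: float):
    X = np.vstack(
        [c + sd * rng.standard_normal((n_per, centers.shape[1])) for c in centers]
    )
    y = np.repeat(np.arange(len(centers)), n_per)
    return X, y
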