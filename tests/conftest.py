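import numpy as np
import pytest

from stagessm.inference import MCMCConfig, build_likelihood, fit
from stagessm.synthetic_data import StudyConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A short, well-behaved dataset for inference unit tests (8 cohorts)."""
    return generate_dataset(StudyConfig(T=8, seed=42))


@pytest.fixture(scope="session")
def small_fit(small_dataset):
    """One modest-budget scenario-1 fit shared across inference unit tests."""
    model = build_likelihood(
        small_dataset.observed,
        small_dataset.covariates,
        scenario=1,
        nA0=small_dataset.config.nA0,
    )
    return fit(model, MCMCConfig(n_steps=1500, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
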