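import numpy as np
import pandas as pd
import pytest

from mitohet import (
    HeteroplasmyModel,
    SyntheticStudyConfig,
    assemble_feature_table,
    generate_study,
)


@pytest.fixture(scope="session")
def zero_noise_config() -> SyntheticStudyConfig:
    return SyntheticStudyConfig(seed=3).without_noise()


@pytest.fixture(scope="session")
def zero_noise_bundle(zero_noise_config):
    return generate_study(zero_noise_config)


@pytest.fixture(scope="session")
def zero_noise_table(zero_noise_bundle) -> pd.DataFrame:
    return assemble_feature_table(zero_noise_bundle)


@pytest.fixture(scope="session")
def noisy_table() -> pd.DataFrame:
    return assemble_feature_table(generate_study(SyntheticStudyConfig(seed=11)))


@pytest.fixture(scope="session")
def quick_result(noisy_table):
    """One short (but converged-enough for smoke checks) posterior fit."""
    return HeteroplasmyModel(noisy_table).fit(seed=11, nsteps=500, burn=200)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
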