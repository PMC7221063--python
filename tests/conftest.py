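import numpy as np
import pytest

from emgforce import (
    DBNConfig,
    ExperimentConfig,
    ForceProfile,
    MuscleModel,
    synthesize_cycle,
    synthesize_session,
)


@pytest.fixture(scope="session")
def clean_cycle():
    """One noise-free-ish 60 %MVC cycle with a clearly dominant grid 0."""
    model = MuscleModel(seed=7)
    profile = ForceProfile(amplitude_fraction=0.6)
    return synthesize_cycle(model, profile, seed=7)


@pytest.fixture(scope="session")
def small_session():
    """3 levels x 4 reps at full rate, default muscle model."""
    model = MuscleModel(seed=3)
    return model, synthesize_session(model, reps_per_level=4)


@pytest.fixture()
def fast_dbn_config():
    """Cut-down training schedule for unit tests."""
    return DBNConfig(pretrain_epochs=3, finetune_epochs=30, patience=10)


@pytest.fixture()
def fast_experiment_config(fast_dbn_config):
    return ExperimentConfig(
        levels=(0.6,), reps_per_level=4, n_validation=1, dbn=fast_dbn_config, seed=3
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
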