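import warnings

import numpy as np
import pytest

from cogrel import synth
from cogrel.fitting import ModelSpec, SamplerSettings, fit_per_session

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=RuntimeWarning)


@pytest.fixture(scope="session")
def small_bandit_study():
    """Twelve-subject two-session bandit dataset with known parameters."""
    spec = synth.default_bandit_population(n_subjects=12)
    return synth.simulate_study(bandit_spec=spec, gamble_spec=None, seed=101)


@pytest.fixture(scope="session")
def small_gamble_study():
    """Twelve-subject two-session gambling dataset with known parameters."""
    spec = synth.default_gamble_population(n_subjects=12)
    return synth.simulate_study(bandit_spec=None, gamble_spec=spec, seed=102)


@pytest.fixture(scope="session")
def quick_settings():
    return SamplerSettings(chains=2, warmup=300, draws=300)


@pytest.fixture(scope="session")
def bandit_posterior_s1(small_bandit_study, quick_settings):
    """Session-1 hierarchical fit of the winning bandit model."""
    return fit_per_session(ModelSpec.bandit_winning(), small_bandit_study.bandit,
                           session=1, settings=quick_settings, seed=7)


@pytest.fixture(scope="session")
def gamble_posterior_s1(small_gamble_study, quick_settings):
    """Session-1 hierarchical fit of the winning prospect-theory model."""
    return fit_per_session(ModelSpec.gamble_winning(), small_gamble_study.gamble,
                           session=1, settings=quick_settings, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
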