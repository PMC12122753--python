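import numpy as np
import pandas as pd
import pytest

from claimseg import synthetic as S


@pytest.fixture(scope="session")
def spec():
    return S.default_latent_class_spec()


@pytest.fixture(scope="session")
def small_sim():
    """300 planted cohort members + 60 distractors (20 per archetype)."""
    config = S.SimulationConfig(n_patients=300, n_distractors=60, seed=11)
    return S.simulate(config, seed=11)


@pytest.fixture(scope="session")
def profiles_5k(spec):
    profiles, labels = S.sample_indicator_profiles(spec, 5000, seed=1)
    return profiles, labels


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
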