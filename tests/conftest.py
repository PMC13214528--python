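import numpy as np
import pytest

from audsurp.synthetic import GroundTruth, SyntheticConfig, generate_trial_features


@pytest.fixture(scope="session")
def small_music_study():
    """One small Music-style study shared across tests (2 subjects x 32 trials)."""
    config = SyntheticConfig.music(n_subjects=2, n_trials_per_session=32, seed=7)
    truth = GroundTruth()
    records, features = generate_trial_features(config, truth)
    return config, truth, records, features


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
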