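import numpy as np
import pytest

import gazedecode as gd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_faces():
    """A small deterministic stimulus set: 4 expressions × 6 identities."""
    return gd.generate_faces(n_identities=6, seed=7)


@pytest.fixture(scope="session")
def noise_image():
    r = np.random.default_rng(0)
    return gd.StimulusImage(r.random((200, 200)), identity="n0", expression="neutral")


@pytest.fixture(scope="session")
def small_experiment():
    """Planted-signal session small enough for unit tests (384 trials)."""
    design = gd.TrialDesign(n_repeats=24, catch_repeats=0)
    exp0 = gd.generate_experiment(n_identities=10, design=design,
                                  feature_space="fourier", seed=21)
    model = gd.make_planted_model(384, k=10, seed=5,
                                  feature_variances=exp0.diffs.var(axis=0))
    return gd.generate_experiment(n_identities=10, design=design, model=model,
                                  feature_space="fourier", seed=21,
                                  target_bayes=0.80)


@pytest.fixture(scope="session")
def fast_config():
    """Reduced wrapper settings for unit-test speed."""
    return gd.SelectionConfig(subsample_size=8, max_budget=12)
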