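import warnings

import numpy as np
import pytest

import crossarea as ca

warnings.filterwarnings("ignore", category=RuntimeWarning,
                        message=".*lambda_max.*")


@pytest.fixture(scope="session")
def small_session():
    """A modest late-stage synthetic session shared by read-only tests."""
    cfg = ca.SyntheticConfig(n_units={"M2": 15, "M1": 15}, n_trials=40,
                             seed=11)
    return ca.generate_session(cfg, "late")


@pytest.fixture(scope="session")
def small_fit(small_session):
    session, truth = small_session
    fit = ca.pipeline.fit_session(session, n_shuffles=200, seed=0)
    return session, truth, fit


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
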