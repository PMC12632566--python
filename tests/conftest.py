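import numpy as np
import pytest

from thetaspeech import synthgen


@pytest.fixture(scope="session")
def default_session():
    """A 60 s synthetic session under the default study conditions."""
    cfg = synthgen.SessionConfig(duration_s=60.0, seed=1)
    return synthgen.make_session(cfg)


@pytest.fixture(scope="session")
def clean_session():
    """60 s session without error trials (clean coupling conditions)."""
    cfg = synthgen.SessionConfig(duration_s=60.0, seed=2,
                                 error_trial_fraction=0.0)
    return synthgen.make_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
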