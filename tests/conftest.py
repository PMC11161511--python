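import numpy as np
import pytest

from bfphys.synthetic import ResponseProfile, SessionConfig, generate_session


@pytest.fixture(scope="session")
def learner_session():
    """A default learner session: mixed cues, differential licking."""
    trials, licks = generate_session(SessionConfig(n_trials=120, seed=11))
    return trials, licks


@pytest.fixture(scope="session")
def punishment_session():
    """Cue 2 only (65% punishment), sized for ~80 punishment trials."""
    trials, licks = generate_session(SessionConfig(n_trials=125, p_cue1=0.0, seed=7))
    return trials, licks


@pytest.fixture
def punishment_responder_profile():
    return ResponseProfile(baseline_rate=5.0, gains={"punishment": 4.0})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
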