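import numpy as np
import pytest

from engage import synthgen as sg


@pytest.fixture(scope="session")
def explorer_trials():
    """One explorer mouse, 5000 trials, with latents and outcomes."""
    cfg = sg.TaskConfig(n_trials=5000, seed=11)
    return sg.simulate_agent(sg.gen_trial_sequence(cfg),
                             sg.explorer_params(), seed=12)


@pytest.fixture(scope="session")
def short_sleep_recording():
    """A 2-h undisturbed synthetic sleep session."""
    return sg.simulate_sleep_session(sg.SleepGenConfig(duration_h=2.0, seed=21))


@pytest.fixture(scope="session")
def arousal_recording():
    """A 4-h synthetic sleep session with arousal tones."""
    return sg.simulate_sleep_session(
        sg.SleepGenConfig(duration_h=4.0, tones=True, seed=22))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
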