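import numpy as np
import pytest

from ramplab.synth import GeneratorConfig, generate_session, generate_trials, substream


@pytest.fixture(scope="session")
def day1_session():
    """One two-interval session (8 units/area, 20 trials/interval) with truth."""
    config = GeneratorConfig(n_units_per_area=8, n_trials_per_interval=20, seed=42)
    session, truth = generate_session(config, "ratA", 1, seed=42)
    return config, session, truth


@pytest.fixture(scope="session")
def fi12_trials_20():
    """20 FI12 trials from a day-0 session (shared light fixture)."""
    config = GeneratorConfig(n_trials_per_interval=20)
    trials, starts = generate_trials(config, 0, substream(7, "trials"))
    return config, trials, starts


def press_train(rng, start, T, rate_low=0.05, rate_high=1.0):
    """Two-state press train helper mirroring the behavior model."""
    n_pre = rng.poisson(rate_low * start)
    pre = np.sort(rng.uniform(0.0, start, size=n_pre))
    post = []
    t = start
    while True:
        t += rng.exponential(1.0 / rate_high)
        post.append(t)
        if t > T:
            break
    return np.unique(np.concatenate([pre, np.asarray(post)]))
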