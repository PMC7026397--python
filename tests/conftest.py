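import numpy as np
import pytest

from attnspot import synth


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def make_session(seed=1, n_trials=120, f_gen=9.0, **overrides):
    """High-SNR spiking session used across decoding/rhythm tests."""
    kwargs = dict(
        n_trials=n_trials,
        f_gen=f_gen,
        p_gen_deg=-75.0,
        distractor_prob=0.0,
        cueoff_to_target_range_ms=(1300, 3300),
    )
    kwargs.update(overrides)
    config = synth.GeneratorConfig(**kwargs)
    return synth.generate_session(config, seed=seed)


@pytest.fixture(scope="session")
def spiking_session():
    return make_session(seed=1, n_trials=120)


@pytest.fixture(scope="session")
def outcome_pool():
    """Large behavioral-only pool with phase-gated outcomes (no spikes)."""
    config = synth.GeneratorConfig(
        n_trials=4000,
        f_gen=9.0,
        hit_base=0.6975,
        hit_depth=0.0525,
        phi_opt_deg=-40.0,
        distractor_prob=0.0,
    )
    return synth.generate_session(config, seed=7, with_spikes=False,
                                  with_trajectories=False)
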