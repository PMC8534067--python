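import numpy as np
import pytest

import oculoml.simulate as sim


def noiseless(params_factory, **extra):
    """Kinematic params with every stochastic nuisance switched off."""
    base = dict(noise_sd_deg=0.0, blink_prob=0.0, drift_left_deg=0.0,
                drift_right_deg=0.0, drift_sd_deg=0.0, duration_jitter=0.0)
    base.update(extra)
    return params_factory(**base)


@pytest.fixture
def noiseless_vergence_params():
    return noiseless(sim.default_vergence_params)


@pytest.fixture
def noiseless_saccade_params():
    return noiseless(sim.default_saccade_params, disconjugacy_deg=0.0,
                     disconjugacy_sd_deg=0.0)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny default-condition cohort shared by pipeline-level tests."""
    spec = sim.CohortSpec(n_control=5, n_dyslexic=5, trials_per_condition=8,
                          n_words=60, seed=17)
    return sim.generate_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
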