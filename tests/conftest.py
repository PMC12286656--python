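"""Shared fixtures: one small seeded synthetic session reused across tests."""

import numpy as np
import pytest

from affectdyn import synth


@pytest.fixture(scope="session")
def small_truth():
    return synth.default_ground_truth(seed=7, n_units=40, n_channels=6)


@pytest.fixture(scope="session")
def small_schedule():
    return synth.make_event_schedule(
        n_trials_pre=4, n_trials_post=4, n_trials_recovery=2, seed=7,
        inter_trial_range=(45.0, 60.0),
    )


@pytest.fixture(scope="session")
def small_activity(small_schedule, small_truth):
    return synth.simulate_population(small_schedule, small_truth, noise_sd=1.0)


@pytest.fixture(scope="session")
def small_eyes(small_schedule, small_truth):
    return synth.simulate_eye_trace(small_schedule, small_truth, noise_sd=0.02)


def assert_allclose(a, b, **kw):
    np.testing.assert_allclose(a, b, **kw)
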