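import numpy as np
import pytest

import ringmotion as rm


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mf_small_ensemble():
    """Six 120-s six-agent trials generated by the mean-field model."""
    settings = rm.SimSettings(
        n_agents=6, model="MF", params=rm.ParamSet(lambda0=-7.5, w_neg=0.76),
        duration_s=120.0, seed=11)
    return rm.run_ensemble(settings, 6)


@pytest.fixture(scope="session")
def mf_small_data(mf_small_ensemble):
    return rm.FineScaleData([r.trajectory for r in mf_small_ensemble],
                            [r.record for r in mf_small_ensemble])


def make_trajectory(theta, frame_rate=7.5, trial_id="t0"):
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if theta.shape[0] == 1:
        theta = theta.T
    times = np.arange(theta.shape[0]) / frame_rate
    return rm.TrialTrajectory(trial_id, frame_rate, times, theta % (2 * np.pi))
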