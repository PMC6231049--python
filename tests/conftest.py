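import numpy as np
import pytest

from fingerbmi.signal_prep import KinematicSeries, SpikeCountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ar1_kinematics(n_bins, a=0.86, sigma=0.1, dt=0.05, rng=None, n_dof=1):
    """AR(1) velocity series integrated into positions (simple test signal)."""
    rng = rng or np.random.default_rng(0)
    vel = np.zeros((n_bins, n_dof))
    for t in range(1, n_bins):
        vel[t] = a * vel[t - 1] + rng.normal(0, sigma, size=n_dof)
    pos = 0.5 + np.cumsum(vel * dt, axis=0)
    return KinematicSeries(dt=dt, positions=pos, velocities=vel)


def make_linear_counts(kinematics, C, rng, noise_sd=1.0):
    """Gaussian-noise counts from a linear tuning model (rounded, floored at 0)."""
    X = np.hstack([kinematics.positions, kinematics.velocities,
                   np.ones((kinematics.n_bins, 1))])
    y = X @ C.T + rng.normal(0, noise_sd, size=(kinematics.n_bins, C.shape[0]))
    return SpikeCountMatrix(dt=kinematics.dt,
                            counts=np.maximum(np.round(y), 0).astype(int))
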