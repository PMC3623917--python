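import numpy as np
import pytest

from pesrough import EnergySeries, OUComponent, SyntheticModel, TrajectorySet, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_series():
    return EnergySeries("t0", 1.0, np.arange(6.0), np.arange(6.0)[::-1].copy())


def make_single_ou(theta=50.0, A=1.0, B=1.0, rho=-0.5, n_steps=10_000, seed=0,
                   delta=1.0, mu_p=0.0, mu_w=0.0):
    return SyntheticModel(
        components=(OUComponent(theta, A, B, rho),),
        baseline_p=mu_p, baseline_w=mu_w,
        sampling_interval=delta, n_steps=n_steps, seed=seed,
    )


@pytest.fixture
def trajectory_pair():
    """Two synthetic trajectories of different lengths on a shared grid."""
    s1 = simulate(make_single_ou(n_steps=1000, seed=1))
    s2 = simulate(make_single_ou(n_steps=3000, seed=2))
    return TrajectorySet([s1, s2])
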