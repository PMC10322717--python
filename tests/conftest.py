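import numpy as np
import pytest

from camopath import synth
from camopath.core import AreaMatrix, TrajectoryTruth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """A 60-disc scene with 3 interdigitated components."""
    return synth.gen_scene(
        60, (256, 256), 54.0, k_components=3, seed=11, layout="interdigitated"
    )


@pytest.fixture(scope="session")
def planted_areas(small_scene):
    """Area matrix with 3 planted sinusoidal components, 10% noise."""
    T = 300
    t = np.arange(T) / 25.0
    loadings = np.stack(
        [10 + 3 * np.sin(2 * np.pi * (0.15 + 0.07 * k) * t + 2 * k) for k in range(3)]
    )
    return synth.gen_component_timeseries(small_scene, T, loadings, 0.3, seed=5)


def planted_component_matrix(N, K, T=300, noise_frac=0.10, seed=0):
    """Balanced-ish planted components with sinusoid loadings (amplitude 3)."""
    rng = np.random.default_rng(seed)
    t = np.arange(T) / 25.0
    loadings = np.stack(
        [10 + 3 * np.sin(2 * np.pi * (0.15 + 0.07 * k) * t + 2 * np.pi * k / K)
         for k in range(K)]
    )
    labels = rng.integers(0, K, N)
    labels[:K] = np.arange(K)
    rng.shuffle(labels)
    vals = loadings[labels].T + rng.normal(0, noise_frac * 3, (T, N))
    return AreaMatrix(np.clip(vals, 0, None)), labels


def make_trajectory(model, seed, noise=0.2, n_waypoints=10, T=900, dwell=20):
    """One planted transition trajectory plus its truth object."""
    truth = TrajectoryTruth(
        model=model,
        start=np.array([0.0, 0.0]),
        goal=np.array([100.0, 60.0]),
        noise_sd=noise,
        n_waypoints=n_waypoints,
        dwell_frames=dwell,
    )
    traj = synth.gen_transition_trajectory(truth, T, seed=seed)
    return traj, truth
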