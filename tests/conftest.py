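import numpy as np
import pytest

import mobilegait as mg


@pytest.fixture(scope="session")
def small_config() -> mg.SimulationConfig:
    return mg.SimulationConfig(n_subjects=3, seed=7)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> mg.GaitDataset:
    return mg.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def clean_config() -> mg.SimulationConfig:
    """Noise-free configuration for geometric checks."""
    return mg.SimulationConfig(n_subjects=2, seed=3, keypoint_jitter_sd=0.0,
                               depth_noise_sd=0.0, occlusion_prob=0.0)


@pytest.fixture(scope="session")
def random_series() -> list[np.ndarray]:
    """50 seeded random series of length 30 with diverse structure.

    Mix of white noise, trends, periodic signals, heavy tails and integer
    (tied) values so degenerate branches of the calculators get exercised.
    """
    rng = np.random.default_rng(2024)
    out: list[np.ndarray] = []
    t = np.arange(30)
    for i in range(50):
        kind = i % 5
        if kind == 0:
            x = rng.normal(size=30)
        elif kind == 1:
            x = 0.2 * t + rng.normal(scale=0.5, size=30)
        elif kind == 2:
            x = np.sin(2 * np.pi * t / rng.integers(3, 12)) \
                + rng.normal(scale=0.1, size=30)
        elif kind == 3:
            x = rng.standard_t(df=2, size=30) * 10
        else:
            x = rng.integers(-3, 4, size=30).astype(float)
        out.append(x)
    return out
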