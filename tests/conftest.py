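"""Shared fixtures: benchmark series that several test modules reuse."""

import numpy as np
import pytest

from trunkmotion.simulate import benettin_lyapunov, simulate_lorenz

LORENZ_SEED = 2024


@pytest.fixture(scope="session")
def lorenz_series() -> np.ndarray:
    """x-coordinate of the Lorenz system: 30,000 samples at dt = 0.01."""
    return simulate_lorenz(n=30000, dt=0.01, seed=LORENZ_SEED)


@pytest.fixture(scope="session")
def lorenz_lambda_ref() -> float:
    """Benettin tangent-space estimate of the largest Lyapunov exponent."""
    return benettin_lyapunov(dt=0.01, n_steps=50000, seed=LORENZ_SEED)


@pytest.fixture(scope="session")
def sinusoid_600() -> np.ndarray:
    """Noise-free sinusoid sampled at 600 points per period, 30 periods."""
    return np.sin(2 * np.pi * np.arange(18000) / 600.0)
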