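import numpy as np
import pytest

from spiralcine.synthetic import PhantomConfig, generate_coil_maps, generate_phantom


@pytest.fixture(scope="session")
def tiny_config() -> PhantomConfig:
    return PhantomConfig(
        grid_size=64,
        crop_size=48,
        n_frames_per_cycle=4,
        n_cycles=1,
        n_coils=4,
        contraction_amplitude=0.3,
        noise_sigma=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_phantom(tiny_config):
    return generate_phantom(tiny_config)


@pytest.fixture(scope="session")
def tiny_maps(tiny_config):
    return generate_coil_maps(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


class ZeroModel:
    """Score model stub that always predicts zero noise."""

    dtype = np.float64

    def forward(self, x, sigma):
        self._shape = np.asarray(x).shape
        return np.zeros_like(np.asarray(x, dtype=float))

    def backward(self, dy):
        return np.zeros(self._shape)


class GaussianScoreModel:
    """Exact noise-predictor for x0 ~ N(mu, s^2 I) (elementwise).

    For x_sigma = x0 + sigma z the optimal prediction is
    eps_hat = sigma (x_sigma - mu) / (s^2 + sigma^2); the induced score is
    the exact Gaussian score of the noised marginal.
    """

    dtype = np.float64

    def __init__(self, mu=0.0, s=1.0):
        self.mu, self.s = mu, s

    def forward(self, x, sigma):
        self._sigma = sigma
        return sigma * (np.asarray(x) - self.mu) / (self.s**2 + sigma**2)

    def backward(self, dy):
        return self._sigma * np.asarray(dy) / (self.s**2 + self._sigma**2)


@pytest.fixture()
def zero_model():
    return ZeroModel()
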