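"""Shared fixtures: small phantoms generated once per session."""

import numpy as np
import pytest

from preful.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def phantom64():
    """Default (noisy) 64x64 phantom, 200 frames."""
    cfg = PhantomConfig(grid_size=(64, 64), n_frames=200, resp_amplitude=4.0, seed=3)
    series, truth = generate_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def phantom64_clean():
    """Noiseless 64x64 phantom for recovery checks."""
    cfg = PhantomConfig(grid_size=(64, 64), n_frames=200, resp_amplitude=4.0,
                        seed=3, noise_sigma=0.0)
    series, truth = generate_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def phantom128():
    """Default-resolution noisy phantom (128x128, 200 frames)."""
    cfg = PhantomConfig(seed=3)
    series, truth = generate_phantom(cfg)
    return cfg, series, truth


@pytest.fixture(scope="session")
def smooth_texture():
    """A smooth random texture for registration tests."""
    from scipy import ndimage
    rng = np.random.default_rng(0)
    return ndimage.gaussian_filter(rng.normal(size=(96, 96)), 4)
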