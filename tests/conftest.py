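import numpy as np
import pytest

from imagecca.cae import CAEConfig, train_cae
from imagecca.fixtures import generate_tissue_image


def _window_stack(n_windows: int, seed: int = 0) -> np.ndarray:
    """Crop 128x128 windows from a few synthetic tissue images."""
    rng = np.random.default_rng(seed)
    wins = []
    n_images = max(1, n_windows // 25)
    for i in range(n_images):
        density = 60 * np.exp(0.3 * rng.standard_normal())
        img = generate_tissue_image(density, 3.0, size=(256, 256), seed=seed * 101 + i)
        for _ in range(int(np.ceil(n_windows / n_images))):
            r, c = rng.integers(0, 128, 2)
            wins.append(img[r:r + 128, c:c + 128].astype(np.float32) / 255.0)
    return np.stack(wins[:n_windows])


@pytest.fixture(scope="session")
def tissue_windows():
    """64 structured 128x128 windows (shared; treat as read-only)."""
    return _window_stack(64, seed=3)


@pytest.fixture(scope="session")
def training_windows_200():
    """200 structured 128x128 windows for trainability checks."""
    return _window_stack(200, seed=11)


@pytest.fixture(scope="session")
def tiny_cae_config():
    return CAEConfig(base_filters=2, code_dim=32, epochs=2, batch_size=32, seed=0)


@pytest.fixture(scope="session")
def trained_tiny_cae(tissue_windows, tiny_cae_config):
    """A briefly trained compact autoencoder shared by encoder-level tests."""
    model, history = train_cae(tissue_windows, tiny_cae_config)
    return model, history
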