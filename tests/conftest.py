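import numpy as np
import pytest

from latentnets import SimConfig, VAEConfig, generate_dataset, train


def two_class_config(seed: int = 7, n_per_class=(60, 40), noise_sd=0.05) -> SimConfig:
    """Two well-separated pulse morphologies, length 140."""
    return SimConfig(
        n_classes=2,
        n_per_class=tuple(n_per_class),
        series_length=140,
        pulse_centers_by_class=((0.25, 0.5), (0.35, 0.7)),
        pulse_amplitudes_by_class=((1.0, -0.6), (-0.8, 1.2)),
        pulse_width=0.04,
        noise_sd=noise_sd,
        seed=seed,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """50 series, 2 classes — shared training fixture."""
    return generate_dataset(two_class_config(seed=3, n_per_class=(30, 20)))


@pytest.fixture(scope="session")
def small_vae_config():
    return VAEConfig(
        latent_dim=8, hidden_units=32, batch_size=16, learning_rate=3e-3,
        max_epochs=30, patience=30, seed=11,
    )


@pytest.fixture(scope="session")
def small_model(small_dataset, small_vae_config):
    """A briefly trained model reused across tests (30 epochs)."""
    return train(small_dataset, small_vae_config)


def random_spd(rng: np.random.Generator, d: int, scale: float = 1.0) -> np.ndarray:
    """Random SPD matrix A A^T + eps I with controlled conditioning."""
    A = rng.normal(size=(d, d)) * scale
    return A @ A.T + (0.1 * scale**2) * np.eye(d)
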