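import numpy as np
import pytest

from cgad import SynthSpec, TrainingConfig, generate_dataset, load_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


def _make_dataset(tmp_factory, name, **spec_kwargs):
    out = tmp_factory.mktemp(name)
    generate_dataset(SynthSpec(**spec_kwargs), out)
    train = load_dataset(out, "train", seed=1)
    test = load_dataset(out, "test", seed=1)
    return train, test


@pytest.fixture(scope="session")
def separable_dataset(tmp_path_factory):
    """Two well-separated classes (ambiguity 0): Bayes error ~ 0 by construction."""
    return _make_dataset(
        tmp_path_factory, "separable", n_per_class=48, K=2, image_size=64,
        ambiguity=0.0, seed=11,
    )


@pytest.fixture(scope="session")
def ambiguous_dataset(tmp_path_factory):
    """High-ambiguity classes: heterogeneous prediction confidence."""
    return _make_dataset(
        tmp_path_factory, "ambiguous", n_per_class=24, K=2, image_size=48,
        ambiguity=0.8, seed=13,
    )


def tiny_config(**overrides) -> TrainingConfig:
    """Desk-scale architecture small enough for second-scale unit tests."""
    base = dict(
        epochs=2, batch_size=8, base_channels=8, latent_dim=16,
        denoiser_width=64, denoiser_depth=2, T=50, seed=3, n_classes=2,
    )
    base.update(overrides)
    return TrainingConfig(**base)
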