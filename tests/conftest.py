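import numpy as np
import pytest

from patternreg import GeneratorConfig, generate_dataset, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def small_config(**overrides):
    """A fast, fully-specified generator configuration for unit tests."""
    kw = dict(
        grid_shape=(6, 6, 3),
        mask_kind="full",
        n_subjects=16,
        n_blobs=1,
        blob_sigma_mm=6.0,
        noise_sd=0.3,
        seed=7,
    )
    kw.update(overrides)
    return GeneratorConfig(**kw)


@pytest.fixture
def small_study(tmp_path):
    """A tiny on-disk study (volumes + tables + atlas) plus ground truth."""
    cfg = small_config()
    paths, truth = generate_study(cfg, tmp_path / "study")
    return cfg, paths, truth


@pytest.fixture
def small_dataset():
    """The same tiny study assembled in memory."""
    cfg = small_config()
    ds, truth = generate_dataset(cfg)
    return cfg, ds, truth


def linear_toy(n, V, noise_sd, seed, weight_scale=1.0):
    """y = X w + eps with dense Gaussian features: an OLS-friendly oracle
    problem for checking the kernel machinery."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, V))
    w = weight_scale * rng.standard_normal(V)
    y = X @ w + noise_sd * rng.standard_normal(n)
    return X, y, w
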