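import numpy as np
import pytest

from nirseed.io import SpectralDataset, partition, white_correct
from nirseed.simulate import default_config, make_grid, simulate_dataset


def corrected_dataset(config) -> SpectralDataset:
    """Simulate a bundle and return the white-corrected SpectralDataset."""
    bundle = simulate_dataset(config)
    grid = make_grid(config.n_channels, config.wl_min, config.wl_max)
    return SpectralDataset(
        wavelengths=grid,
        X=white_correct(bundle.raw, bundle.white),
        y=bundle.labels,
        ids=[f"k{i:04d}" for i in range(bundle.labels.size)],
    )


@pytest.fixture(scope="session")
def study_dataset() -> SpectralDataset:
    """Default-condition dataset: 200/class, 512 channels, seed 42."""
    return corrected_dataset(default_config(seed=42))


@pytest.fixture(scope="session")
def study_split(study_dataset):
    """The 320/80 stratified split of the default-condition dataset."""
    return partition(study_dataset, 0.8, seed=7)


@pytest.fixture(scope="session")
def small_dataset() -> SpectralDataset:
    """Small 2-class dataset (60 kernels, 64 channels) for fast model tests."""
    cfg = default_config(n_per_class=30, n_channels=64, seed=11)
    return corrected_dataset(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
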