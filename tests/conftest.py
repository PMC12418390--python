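import numpy as np
import pytest

from fmh2st import SyntheticSpec, generate_dataset, preprocess_dataset, toy_backbone


@pytest.fixture(scope="session")
def default_synthetic():
    """The default synthetic scenario: 4 sections x 64 spots x 30 genes."""
    ds, labels = generate_dataset(SyntheticSpec())
    ds = preprocess_dataset(ds, n_hvg=30, min_spots=1)
    return ds, labels


@pytest.fixture(scope="session")
def tiny_section_dataset():
    """One 16-spot, 10-gene section (noise-free) for fast training tests."""
    spec = SyntheticSpec(
        n_sections=1, spots_per_section=16, n_genes=10, image_size=64,
        seed=1, noise_model="none", dispersion=0.0,
    )
    ds, labels = generate_dataset(spec)
    ds = preprocess_dataset(ds, n_hvg=10, min_spots=1)
    return ds, labels


@pytest.fixture(scope="session")
def backbone():
    return toy_backbone()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
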