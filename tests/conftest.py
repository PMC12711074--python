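"""Shared fixtures: small synthetic datasets generated in memory."""

import numpy as np
import pytest

from ccvae.synthetic import SyntheticConfig, generate_in_memory


@pytest.fixture(scope="session")
def default_dataset():
    """Default-condition dataset (confounders and truncations included)."""
    config = SyntheticConfig(n_tracks=24, seed=7)
    manifest, synths = generate_in_memory(config)
    return config, manifest, synths


@pytest.fixture(scope="session")
def clean_dataset():
    """Noise-free, truncation-free, confounder-free dataset."""
    config = SyntheticConfig(n_tracks=10, seed=3, reporter_noise_cv=0.0,
                             reporter_additive_sd=0.0, pixel_noise_sd=0.0,
                             truncation_fraction=0.0, confounder_fraction=0.0)
    manifest, synths = generate_in_memory(config)
    return config, manifest, synths


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
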