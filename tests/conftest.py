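"""Shared fixtures. Heavy synthetic artifacts are session-scoped so the
state-recovery and end-to-end tests reuse one dataset build."""

import numpy as np
import pytest

from mmbn import SyntheticConfig, build_mmbn, generate_dataset
from mmbn.amcnn import networks_to_array


@pytest.fixture(scope="session")
def default_config():
    """The default two-regime generator configuration, seed 7."""
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_windows(default_config):
    """200 windows per state from the default regimes (400 total)."""
    return generate_dataset(200, default_config)


@pytest.fixture(scope="session")
def default_networks(default_windows):
    """Thresholded MMBNs of the default dataset."""
    return [build_mmbn(w) for w in default_windows]


@pytest.fixture(scope="session")
def default_xy(default_networks):
    """Stacked model inputs (n, 23, 23, 8) and labels for the default dataset."""
    return networks_to_array(default_networks)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_windows():
    """A small, quick window set (12 per state, 8 channels) for smoke tests."""
    cfg = SyntheticConfig(n_channels=8, duration=6.0, seed=11)
    return generate_dataset(12, cfg)
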