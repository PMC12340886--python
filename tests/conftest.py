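import numpy as np
import pytest

from komplexnet import datagen as dg


@pytest.fixture(scope="session")
def bank():
    """Small deterministic glyph bank shared across tests."""
    return dg.make_synthetic_glyphs(n_classes=10, size=14, per_class=10, seed=0)


@pytest.fixture(scope="session")
def clean_scenes(bank):
    """Two-object, non-overlapping scenes with masks."""
    return dg.make_dataset(bank, 24, n_objects=2, max_overlap=0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
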