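import numpy as np
import pytest

from qliver import synth


@pytest.fixture
def rng():
    return np.random.default_rng(20210629)


@pytest.fixture
def phantom_15():
    """Quiet 1.5 T abdominal phantom (no iron, no fat)."""
    return synth.default_phantom_spec(1.5, noise_sd=5.0, seed=7)


@pytest.fixture
def multiecho_15(phantom_15):
    series, truth = synth.make_multiecho_series(phantom_15, n_echoes=10)
    return series, truth, synth.default_rois(phantom_15)
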