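import numpy as np
import pytest

from cardiocode.ica import decoding_filters, fastica
from cardiocode.preprocess import whiten
from cardiocode.synthetic import gen_excitations, gen_gabor_bank, synthesize_observations


@pytest.fixture(scope="session")
def tiny_bank():
    """Ground-truth Gabor bank at the tiny fixture scale (M=8, N=64)."""
    return gen_gabor_bank(8, 64, freq_lo=2.0 / 64, seed=7)


@pytest.fixture(scope="session")
def tiny_ensemble(tiny_bank):
    """Dirac-excited observation ensemble synthesized from ``tiny_bank``."""
    exc = gen_excitations(8, 64, 1500, seed=8)
    return synthesize_observations(tiny_bank, exc)


@pytest.fixture(scope="session")
def learned_bank(tiny_ensemble):
    """ICA decoding bank learned from the tiny ensemble."""
    Z, wh = whiten(tiny_ensemble, n_components=8)
    um = fastica(Z, seed=9, max_iter=3000)
    return decoding_filters(um, wh)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
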