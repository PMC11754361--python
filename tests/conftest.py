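import numpy as np
import pytest

from fgsquant import synth


@pytest.fixture()
def noise_free_case():
    """Phantom with exact 3x tumor contrast over a 40-unit background."""
    cfg = synth.PhantomConfig(true_tbr=3.0, background_mfi=40.0, noise_sd=0.0, seed=11)
    return synth.make_phantom(cfg)


@pytest.fixture()
def blob_case():
    """Asymmetric (blobby) phantom suitable for unambiguous shape matching."""
    cfg = synth.PhantomConfig(true_tbr=3.0, noise_sd=2.0, tumor_shape="blob", seed=5)
    return synth.make_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def square_mask(shape=(20, 20), lo=5, hi=15):
    mask = np.zeros(shape, bool)
    mask[lo:hi, lo:hi] = True
    return mask
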