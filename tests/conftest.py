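import numpy as np
import pytest

from poishmm import NaturalParams, fit_ml
from poishmm.datasets import load_tyt

# Published two-state estimates for the TYT arousal series, used as a
# frozen reference point throughout the suite.
TYT_NLL = 168.536055869
TYT_LAM = (1.636410931, 5.533095962)
TYT_G11 = 0.949802041
TYT_G21 = 0.025922044
TYT_DELTA1 = 0.340541816
TYT_AIC = 345.072111738


@pytest.fixture(scope="session")
def tyt():
    return load_tyt()


@pytest.fixture(scope="session")
def tyt_fit(tyt):
    return fit_ml(tyt, 2)


@pytest.fixture(scope="session")
def table2_params():
    return NaturalParams(
        m=2,
        tpm=np.array([[TYT_G11, 1.0 - TYT_G11], [TYT_G21, 1.0 - TYT_G21]]),
        lam=np.array(TYT_LAM),
        init="stationary",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_model(rng, m, lam_scale=6.0):
    """A random strictly positive m-state model for property tests."""
    G = rng.uniform(0.2, 1.0, size=(m, m))
    G /= G.sum(axis=1, keepdims=True)
    lam = np.sort(rng.uniform(0.3, lam_scale, size=m))
    lam += 0.1 * np.arange(m)  # keep means distinct
    return NaturalParams(m=m, tpm=G, lam=lam, init="stationary")
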