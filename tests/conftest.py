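import numpy as np
import pytest

from latentgeom import GaussianCode


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def random_valid_code(rng, n=6, d=3, noiseless=False):
    """Random realizable code (see latentgeom.synth.random_code)."""
    from latentgeom.synth import random_code
    return random_code(n, d, rng, noiseless=noiseless)


@pytest.fixture
def noisy_identity_code():
    """x = z + isotropic noise with unit variance, omega = I_3."""
    d = 3
    return GaussianCode(psi=2.0 * np.eye(d), phi=np.eye(d), omega=np.eye(d))
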