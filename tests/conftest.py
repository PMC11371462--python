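import numpy as np
import pytest

from gtrlink.core_model import ExchangeabilityMatrix, Profile, ProfileMixture


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_exchangeability(rng, low=0.05, high=3.0, name="rand"):
    m = rng.uniform(low, high, (20, 20))
    return ExchangeabilityMatrix(m + m.T, name=name)


def random_profile(rng, concentration=3.0):
    f = rng.dirichlet(np.full(20, concentration))
    return Profile(np.maximum(f, 1e-8) / np.maximum(f, 1e-8).sum())


def random_mixture(rng, C, concentration=3.0):
    profiles = tuple(random_profile(rng, concentration) for _ in range(C))
    w = rng.dirichlet(np.full(C, 5.0))
    return ProfileMixture(profiles, w / w.sum())


def random_codes(rng, n_taxa, n_sites, missing_frac=0.1):
    codes = rng.integers(0, 20, (n_taxa, n_sites)).astype(np.int8)
    mask = rng.random((n_taxa, n_sites)) < missing_frac
    codes[mask] = -1
    return codes
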