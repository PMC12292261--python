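import numpy as np
import pytest

from atlasforge.core import Volume
from atlasforge.phantom import PhantomSpec, make_latent_template, make_population


@pytest.fixture(scope="session")
def latent_small():
    """A 24^3 latent brain with its pure-tissue masks."""
    return make_latent_template((24, 24, 24), seed=0)


@pytest.fixture(scope="session")
def small_population():
    """A 24^3, N=4 population with mild deformations and noise."""
    spec = PhantomSpec(
        shape=(24, 24, 24), n_subjects=4, seed=1,
        deformation_amplitude=2.0, smoothness=4.0, noise_sd=1.0,
    )
    return make_population(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_volume(data) -> Volume:
    return Volume(np.asarray(data, dtype=float))
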