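import numpy as np
import pytest

from nerveseg.phantom import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def default_phantom():
    """One deterministic phantom shared by metric and I/O tests."""
    return generate_phantom(PhantomSpec(seed=7, n_splits=1, n_merges=1))


@pytest.fixture(scope="session")
def small_phantom():
    """A smaller, faster phantom for training smoke tests."""
    spec = PhantomSpec(
        shape=(16, 96, 96),
        n_fascicles_initial=3,
        nerve_ellipse_semiaxes_um=(450.0, 480.0),
        fascicle_radius_range_um=(40.0, 90.0),
        n_splits=0,
        n_merges=0,
        seed=11,
    )
    return generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
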