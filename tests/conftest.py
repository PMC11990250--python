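import numpy as np
import pytest

from deltacca import SyntheticSpec, generate_coupled_views


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticSpec(
        n_subjects=600,
        p_x=30,
        p_y=25,
        k_latent=2,
        canonical_corrs=(0.5, 0.3),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_views(small_spec):
    return generate_coupled_views(small_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
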