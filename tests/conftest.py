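import numpy as np
import pytest

from cilioscope import RunConfig, SyntheticSpec, render_field


@pytest.fixture(scope="session")
def config():
    return RunConfig()


@pytest.fixture(scope="session")
def clean_field():
    """Noise-free, fully ciliated field: the exact-count oracle."""
    spec = SyntheticSpec(
        n_cells=12, frac_ciliated=1.0, frac_spot=0.0,
        noise_gaussian_sd=0.0, seed=3,
    )
    return render_field(spec)


@pytest.fixture(scope="session")
def mixed_field():
    """Noise-free field with the default cilium/spot/none mixture."""
    spec = SyntheticSpec(n_cells=12, noise_gaussian_sd=0.0, seed=11)
    return render_field(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
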