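import numpy as np
import pytest

from memret import MaskSpec, simulate_pattern, two_sphere_density, validate_config


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_pattern():
    """Noiseless fully known 64x64 two-sphere pattern with its ground truth."""
    rho = two_sphere_density(64)
    data, rho_true = simulate_pattern(rho)
    return data, rho_true


@pytest.fixture
def holed_pattern():
    """64x64 two-sphere pattern with a 5-pixel central hole."""
    rho = two_sphere_density(64)
    data, rho_true = simulate_pattern(rho, MaskSpec(central_shape="disk", central_size=5))
    return data, rho_true


@pytest.fixture
def small_config():
    """Fast engine configuration for 64x64 problems."""
    return validate_config(
        dict(sigma_init=44, tau=0.1, p=8, g=10, j_ia=10, j_er=10, j_eval=10,
             seed=1, n_p=64)
    )
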