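import numpy as np
import pytest

from optir_recon import (
    PhantomSpec,
    SamplingScheme,
    interpolate_cube,
    make_phantom,
    reconstruct_cube,
    subsample_y,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def default_truth():
    """Default-condition phantom shared across tests (read-only)."""
    return make_phantom(PhantomSpec(seed=5))


@pytest.fixture(scope="session")
def edge_truth():
    """Edge-rich phantom: sharper boundaries, lower noise."""
    return make_phantom(
        PhantomSpec(rows=120, cols=120, spatial_blur_sigma=0.5, noise_sd=0.005, seed=11)
    )


@pytest.fixture(scope="session")
def s10_reconstruction(default_truth):
    """Interpolated and fused reconstructions of the default phantom at s=10."""
    sparse = subsample_y(default_truth.noisy_cube, SamplingScheme(dy_lo=5.0))
    interp = interpolate_cube(sparse)
    result = reconstruct_cube(sparse)
    return sparse, interp, result
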