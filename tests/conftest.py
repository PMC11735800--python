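import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Small noiseless labelled cohort (4 cells per class)."""
    from scgmp import synthio

    cfg = synthio.TraceDatasetConfig(n_cells=16, noise_sd=0.0)
    return synthio.generate_trace_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def noisy_bundle():
    """Cohort at the default noise level (SNR ~ 10), 10 cells per class."""
    from scgmp import synthio

    cfg = synthio.TraceDatasetConfig(n_cells=40)
    return synthio.generate_trace_dataset(cfg, seed=7)


@pytest.fixture(scope="session")
def gridded_images(noiseless_bundle):
    from scgmp import synthio

    cfg = synthio.ImageConfig(
        rotation_deg=10.0, translation=(12.0, -7.0), if_noise_sd=0.0
    )
    return synthio.generate_gridded_images(noiseless_bundle, cfg, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
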