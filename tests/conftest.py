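import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_dataset():
    """A small 64x64 semi-artificial dataset shared across tests."""
    from cathtrack import DatasetConfig, build_dataset

    cfg = DatasetConfig(n_subjects_train=4, n_subjects_val=2, frames_per_subject=10,
                        negative_fraction=0.10, image_shape=(64, 64), rng_seed=42)
    return build_dataset(cfg)
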