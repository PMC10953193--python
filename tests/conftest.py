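import numpy as np
import pytest

from noduledet.phantom import PhantomConfig, generate_phantom


@pytest.fixture(scope="session")
def small_phantom_cfg() -> PhantomConfig:
    """A compact phantom used by several suites (fast to generate)."""
    return PhantomConfig(volume_shape=(64, 96, 96), n_nodules=3,
                         diameter_median=8.0, diameter_range=(4.0, 16.0), seed=42)


@pytest.fixture(scope="session")
def phantom(small_phantom_cfg):
    return generate_phantom(small_phantom_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
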