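import numpy as np
import pytest

from vitreoquant import SyntheticConfig, generate_volume


def small_config(**overrides) -> SyntheticConfig:
    """Down-scaled scan geometry for fast unit tests."""
    defaults = dict(
        n_scans=5,
        width_px=160,
        height_px=200,
        fovea_dip_px=6.0,
        inflammation_level=2.0,
        speckle_sigma=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def small_cfg():
    return small_config()


@pytest.fixture
def small_volume(small_cfg):
    return generate_volume(small_cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
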