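import numpy as np
import pytest

from qhi.flow import build_k2_lut
from qhi.sfdi import build_rd_lut


@pytest.fixture(scope="session")
def rd_lut():
    """Full-resolution reflectance LUT (512 x 512, standard axis ranges)."""
    return build_rd_lut()


@pytest.fixture(scope="session")
def k2_lut_default():
    """K^2 LUT at the standard axes (256 Db x 128 mu_a x 128 mu_s')."""
    return build_k2_lut(beta=1.0)


@pytest.fixture(scope="session")
def k2_lut_coarse():
    """Small K^2 LUT for cheap inversion tests."""
    return build_k2_lut(beta=0.8, n_db=96, n_mua=48, n_musp=48)


@pytest.fixture
def rng():
    return np.random.default_rng(20230912)
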