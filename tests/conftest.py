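import numpy as np
import pytest

from rrmice import FactorDraw, apply_selection, gen_artificial, gen_natural


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def drr_natural_dataset(rng):
    factors = FactorDraw(rho_xy=0.6, br=0.5)
    return gen_natural(500, factors, "drr", rng)


@pytest.fixture
def drr_artificial_dataset(rng):
    factors = FactorDraw(rho_xy=0.6, br=0.4)
    return gen_artificial(500, factors, "drr", rng)


@pytest.fixture
def irr_natural_dataset(rng):
    factors = FactorDraw(rho_xy=0.6, br=0.5, rho_zx=0.4, rho_zy=0.5)
    return gen_natural(500, factors, "irr", rng)


@pytest.fixture
def restricted_half(drr_natural_dataset):
    return apply_selection(drr_natural_dataset, 0.5)
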