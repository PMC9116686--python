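import numpy as np
import pytest

from pgsturnover import GwasDesign, PopGenParams, TraitModel


@pytest.fixture
def small_params() -> PopGenParams:
    """Symmetric-mutation parameters small enough for brute-force checks."""
    return PopGenParams.from_scaled(0.05, two_N=400)


@pytest.fixture
def small_design() -> GwasDesign:
    return GwasDesign.symmetric(n=200, d=20)


@pytest.fixture
def small_trait() -> TraitModel:
    return TraitModel.from_h2(L=100, beta=0.1, h2=0.5, a=0.05)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
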