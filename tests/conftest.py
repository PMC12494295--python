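import numpy as np
import pytest

from gliasim.params import AdexParams, AstrocyteParams


@pytest.fixture(scope="session")
def astro_params() -> AstrocyteParams:
    return AstrocyteParams()


@pytest.fixture(scope="session")
def adex_params() -> AdexParams:
    return AdexParams()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
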