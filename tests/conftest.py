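import numpy as np
import pytest

from memdomain.vesicle_mc import MCParams, build_vesicle


@pytest.fixture(scope="session")
def tiny_vesicle():
    """A small labelled vesicle reused by mesh-level tests (N=162, rho=0.3)."""
    return build_vesicle(MCParams(n_vertices=162, rho=0.3, seed=3))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
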