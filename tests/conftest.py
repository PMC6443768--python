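import numpy as np
import pytest
from hypothesis import settings

from netrecip import ModelParams, build_lattice

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def reference_params():
    """Reference parameter point: delta = 0.05, normal reciprocity, h = 2."""
    return ModelParams(r=3.0, delta=0.05, d=0.0, h=2)


@pytest.fixture
def small_lattice():
    return build_lattice("square4", 36)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
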