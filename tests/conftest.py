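import numpy as np
import pytest

from bodycomp import config as cfg
from bodycomp.abdomen import segment_vat_sat
from bodycomp.core import DEFAULT_BANDS
from bodycomp.evaluation import make_back_atlas_from_phantoms, make_liver_atlas
from bodycomp.phantom import (
    AbdomenPhantomSpec,
    LiverPhantomSpec,
    ThighPhantomSpec,
    make_phantom,
)


@pytest.fixture(scope="session")
def bands():
    return DEFAULT_BANDS


@pytest.fixture(scope="session")
def abdomen_phantom():
    return make_phantom(AbdomenPhantomSpec(seed=11))


@pytest.fixture(scope="session")
def liver_phantom():
    return make_phantom(LiverPhantomSpec(seed=11))


@pytest.fixture(scope="session")
def thigh_phantom():
    return make_phantom(ThighPhantomSpec(seed=12))


@pytest.fixture(scope="session")
def back_atlas():
    return make_back_atlas_from_phantoms(n=20, seed=903)


@pytest.fixture(scope="session")
def liver_atlas():
    return make_liver_atlas(n=25, seed=503)


@pytest.fixture(scope="session")
def abdomen_result(abdomen_phantom, back_atlas):
    return segment_vat_sat(abdomen_phantom.slice, cfg.ABDOMEN_ILT, back_atlas)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
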