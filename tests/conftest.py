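import numpy as np
import pytest

from hypothesis import settings

import pglsverse as pv

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def paper_like():
    """The frozen 40-species, six-predictor synthetic fixture."""
    return pv.make_fixture("paper-like")


@pytest.fixture(scope="session")
def candidates():
    from pglsverse.simulate import PAPER_LIKE_VARIABLES

    return tuple(PAPER_LIKE_VARIABLES[1:])


@pytest.fixture(scope="session")
def three_tip_tree():
    return pv.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def star_vcv(n, scale=1.0):
    """Star-phylogeny covariance: no shared history."""
    return pv.VCVMatrix([f"t{i}" for i in range(n)], scale * np.eye(n))
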