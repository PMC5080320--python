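import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from indelphase.io import read_newick
from indelphase.models import F84Params, IndelModel


@pytest.fixture
def rng():
    return np.random.default_rng(20160921)


@pytest.fixture
def cherry():
    return read_newick("(A:0.1,B:0.2);")


@pytest.fixture
def three_leaf():
    return read_newick("((A:0.1,B:0.1):0.05,C:0.2);")


@pytest.fixture
def four_leaf():
    return read_newick("((A:0.1,B:0.2):0.05,(C:0.15,D:0.1):0.08);")


@pytest.fixture
def paper_f84():
    """The published residue-block parameter estimates."""
    return F84Params(0.513467, 0.486533,
                     np.array([0.254698, 0.260464, 0.263575, 0.221263]))


@pytest.fixture
def paper_indel_model(paper_f84):
    return IndelModel(0.008509, 0.061660, paper_f84, 0.998058)


def random_f84(rng) -> F84Params:
    pi = rng.dirichlet(np.full(4, 5.0))
    return F84Params(float(rng.uniform(0.05, 2.0)),
                     float(rng.uniform(0.05, 2.0)), pi)


def random_indel_model(rng) -> IndelModel:
    return IndelModel(float(rng.uniform(0.0, 0.5)),
                      float(rng.uniform(0.0, 0.8)),
                      random_f84(rng), float(rng.uniform(0.6, 0.999)))
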