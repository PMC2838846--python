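import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from kinomeprofiler.profile_hmm import ProfileHMM
from kinomeprofiler.synthetic_fixtures import make_domain_library, make_group_library


def random_profile_hmm(L: int, seed: int, name: str = "rand") -> ProfileHMM:
    """A random but valid model: Dirichlet emissions and transitions."""
    r = np.random.default_rng(seed)
    me = r.dirichlet(np.ones(20) * 0.5, size=L)
    ie = r.dirichlet(np.ones(20), size=L + 1)
    t = np.zeros((L + 1, 7))
    for k in range(L + 1):
        t[k, 0:3] = r.dirichlet(np.ones(3))
        t[k, 3:5] = r.dirichlet(np.ones(2))
        t[k, 5:7] = r.dirichlet(np.ones(2))
    m2 = t[L, 0:2] / t[L, 0:2].sum()
    t[L, 0], t[L, 1], t[L, 2] = m2[0], m2[1], 0.0
    t[0, 5], t[0, 6] = 1.0, 0.0
    t[L, 5], t[L, 6] = 1.0, 0.0
    return ProfileHMM(
        name=f"{name}{seed}", length=L, match_emissions=me, insert_emissions=ie,
        transitions=t, null_model=r.dirichlet(np.ones(20) * 5),
    )


@pytest.fixture(scope="session")
def group_library():
    return make_group_library(seed=1)


@pytest.fixture(scope="session")
def domain_library():
    return make_domain_library(seed=2)
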