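import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sibphase.pedigree import decompose
from sibphase.simulate import StructureSpec, simulate


@pytest.fixture(scope="session")
def small_fullsib_sim():
    """One mating, 5 offspring, 30 markers: shared cheap fixture."""
    return simulate(StructureSpec(1, 1, 5, n_markers=30, seed=11))


@pytest.fixture()
def trio_chain(small_fullsib_sim):
    chains = decompose(small_fullsib_sim.pedigree, 1)
    return chains[0]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
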