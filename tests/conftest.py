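import numpy as np
import pytest

from cgfold.mapping import MappingScheme
from cgfold.fixtures import table2_forcefield, toy_peptide, default_bonded


@pytest.fixture(scope="session")
def scheme():
    return MappingScheme.default()


@pytest.fixture(scope="session")
def softcore():
    pots, minima = table2_forcefield()
    return pots


@pytest.fixture(scope="session")
def pair_minima():
    _, minima = table2_forcefield()
    return minima


@pytest.fixture(scope="session")
def mixed_peptide(scheme):
    """10-residue mixed-sequence toy chain exercising every site type."""
    seq = ["ALA", "TRP", "GLU", "LYS", "SER", "LEU", "ARG", "THR", "TYR", "VAL"]
    topo, X = toy_peptide(seq, "extended", scheme)
    return topo, X


@pytest.fixture(scope="session")
def bonded_ff():
    return default_bonded()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
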