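import numpy as np
import pytest

from foldchron.census import (
    CensusMatrix,
    DomainFamily,
    SupergroupLabel,
)
from foldchron.coding import CharacterMatrix


def make_cm(rows, labels=None, n_states=24, codes=None):
    """Character matrix from a plain list of state rows (taxa x characters)."""
    rows = np.asarray(rows)
    labels = labels or [f"t{i}" for i in range(rows.shape[0])]
    codes = codes or ["A"] * rows.shape[1]
    return CharacterMatrix(
        taxa=[DomainFamily(l) for l in labels],
        characters=[(f"c{j}", SupergroupLabel(codes[j])) for j in range(rows.shape[1])],
        states=rows,
        n_states=n_states,
    )


def make_census(counts, labels=None, codes=None):
    counts = np.asarray(counts)
    labels = labels or [f"f{i}" for i in range(counts.shape[0])]
    codes = codes or ["A"] * counts.shape[1]
    proteomes = [(f"p{j}", SupergroupLabel(codes[j])) for j in range(counts.shape[1])]
    return CensusMatrix(
        taxa=[DomainFamily(l) for l in labels],
        proteomes=proteomes,
        abundance=counts,
    )


@pytest.fixture
def cm_factory():
    return make_cm


@pytest.fixture
def census_factory():
    return make_census


@pytest.fixture(scope="session")
def paper_fixture():
    from foldchron.simulate import default_paper_fixture

    return default_paper_fixture()
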