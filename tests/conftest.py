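import numpy as np
import pandas as pd
import pytest

from phylostruct import Metacommunity, Phylogeny, TraitTable


@pytest.fixture
def balanced_tree():
    return Phylogeny.from_newick("((A,B),(C,D));")


@pytest.fixture
def cherry_tree():
    return Phylogeny.from_newick("(A,(B,C));")


@pytest.fixture
def star_tree():
    return Phylogeny.from_newick("(A,B,C,D);")


@pytest.fixture
def toy_metacommunity():
    """Four sites over four species, two habitats, a latitude gradient."""
    presence = pd.DataFrame(
        [[1, 1, 0, 0],
         [1, 1, 1, 0],
         [0, 0, 1, 1],
         [0, 1, 1, 1]],
        index=["f1", "f2", "n1", "n2"],
        columns=["A", "B", "C", "D"],
    )
    habitat = {"f1": "forest", "f2": "forest",
               "n1": "non_forest", "n2": "non_forest"}
    latitude = {"f1": 5.0, "f2": 10.0, "n1": 20.0, "n2": 25.0}
    return Metacommunity(presence, habitat, latitude)


@pytest.fixture
def toy_traits():
    rng = np.random.default_rng(7)
    data = pd.DataFrame(
        {t: rng.uniform(1, 10, size=4) for t in
         ("SVL", "TL", "CAM", "HL", "HW", "HH", "VS", "SS")},
        index=["A", "B", "C", "D"],
    )
    return TraitTable(data)
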