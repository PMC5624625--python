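import io as _io

import numpy as np
import pandas as pd
import pytest

from gradiv.datamodel import CommunityMatrix, DistanceMatrix, TraitTable
from gradiv.io import read_newick


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — MRCA depths solvable by hand."""
    return read_newick(_io.StringIO("((A:1,B:1):1,C:2);"))


@pytest.fixture
def star_tree():
    return read_newick(_io.StringIO("(A:1,B:1,C:1,D:1);"))


@pytest.fixture
def caterpillar_tree():
    nwk = "((((((((A:1,B:1):1,C:2):1,D:3):1,E:4):1,F:5):1,G:6):1,H:7):1,I:8);"
    return read_newick(_io.StringIO(nwk))


@pytest.fixture
def small_community():
    data = pd.DataFrame(
        [[2.0, 0.0, 1.0], [1.0, 1.0, 0.0], [0.0, 3.0, 4.0]],
        index=["p1", "p2", "p3"],
        columns=["A", "B", "C"],
    )
    return CommunityMatrix(data)


@pytest.fixture
def trait_table():
    rng = np.random.default_rng(0)
    species = [f"sp{i}" for i in range(8)]
    data = pd.DataFrame(
        {
            "max_height": rng.lognormal(1.5, 0.5, 8),
            "leaf_length": rng.lognormal(2.0, 0.4, 8),
            "leaf_width": rng.lognormal(1.2, 0.4, 8),
            "flowering_onset": rng.integers(3, 9, 8).astype(float),
            "seed_mass": rng.lognormal(2.3, 1.0, 8),
        },
        index=species,
    )
    return TraitTable(data)


@pytest.fixture
def random_distance():
    rng = np.random.default_rng(1)
    pts = rng.normal(size=(10, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix([f"t{i}" for i in range(10)], d)
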