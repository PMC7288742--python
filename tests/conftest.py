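import dendropy
import numpy as np
import pandas as pd
import pytest

from gypsodiv import (
    CommunityMatrix,
    EnvironmentTable,
    Phylogeny,
    TraitTable,
    validate_dataset,
)


def make_tree(newick: str) -> Phylogeny:
    return Phylogeny(
        dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")
    )


@pytest.fixture
def toy_community() -> CommunityMatrix:
    df = pd.DataFrame(
        [[1.0, 2.0, 0.0, 0.5],
         [0.0, 0.0, 3.0, 1.0],
         [2.0, 0.0, 1.0, 0.0]],
        index=["p1", "p2", "p3"],
        columns=["A", "B", "C", "D"],
    )
    return CommunityMatrix(df)


@pytest.fixture
def toy_traits() -> TraitTable:
    return TraitTable(pd.Series({"A": 2.0, "B": 3.0, "C": 5.0, "D": 4.0}))


@pytest.fixture
def toy_tree() -> Phylogeny:
    return make_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);")


@pytest.fixture
def toy_env() -> EnvironmentTable:
    return EnvironmentTable(
        pd.DataFrame(
            {"Tmax": [31.0, 33.0, 34.0], "MAP": [500.0, 300.0, 200.0],
             "cover": [20.0, 30.0, 40.0]},
            index=["p1", "p2", "p3"],
        )
    )


@pytest.fixture
def toy_dataset(toy_community, toy_traits, toy_tree, toy_env):
    return validate_dataset(toy_community, toy_traits, toy_tree, toy_env)


def star_tree(n: int, length: float = 1.0) -> Phylogeny:
    tips = ",".join(f"t{i}:{length:g}" for i in range(n))
    return make_tree(f"({tips});")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
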