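import dendropy
import numpy as np
import pytest

from m6aevo import ProteinRecord, ScoringScheme, SpeciesTree


@pytest.fixture(scope="session")
def scheme():
    return ScoringScheme()


@pytest.fixture(scope="session")
def blosum(scheme):
    return scheme.matrix


def make_species_tree(newick: str, supergroups: dict) -> SpeciesTree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    return SpeciesTree(tree, supergroups)


@pytest.fixture
def abcd_tree():
    """((A,B),(C,D)) with one supergroup per cherry."""
    return make_species_tree(
        "((A:1,B:1)n2:1,(C:1,D:1)n3:1)n1;",
        {"A": "Amorphea", "B": "Amorphea", "C": "SAR", "D": "SAR"},
    )


def random_protein(rng, length: int, alphabet: str = "ACDEFGHIKLMNPQRSTVWY") -> str:
    letters = np.array(list(alphabet))
    return "".join(letters[rng.integers(len(letters), size=length)])


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
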