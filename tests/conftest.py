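import numpy as np
import pytest

from ipcarf import DiseaseOntology, SyntheticConfig, generate_dataset


@pytest.fixture
def chain_ontology():
    """D -> P -> R."""
    return DiseaseOntology(terms={"D", "P", "R"}, edges={("D", "P"), ("P", "R")})


@pytest.fixture
def diamond_ontology():
    """D -> {P1, P2} -> R."""
    return DiseaseOntology(
        terms={"D", "P1", "P2", "R"},
        edges={("D", "P1"), ("D", "P2"), ("P1", "R"), ("P2", "R")},
    )


@pytest.fixture
def sibling_ontology():
    """D1, D2 both children of root P."""
    return DiseaseOntology(terms={"D1", "D2", "P"}, edges={("D1", "P"), ("D2", "P")})


def random_dag(rng: np.random.Generator, n_nodes: int) -> DiseaseOntology:
    """Random DAG: node i may only point at smaller-numbered nodes (acyclic)."""
    terms = {f"n{i}" for i in range(n_nodes)}
    edges = set()
    for i in range(1, n_nodes):
        n_par = int(rng.integers(1, min(i, 2) + 1))
        for p in rng.choice(i, size=n_par, replace=False):
            edges.add((f"n{i}", f"n{int(p)}"))
    return DiseaseOntology(terms=terms, edges=edges)


@pytest.fixture(scope="session")
def small_dataset():
    """Small planted-block dataset shared by the heavier tests."""
    return generate_dataset(SyntheticConfig(n_lnc=30, n_dis=20, n_terms=30,
                                            n_clusters=3, seed=7))


@pytest.fixture(scope="session")
def default_dataset():
    """The default study-condition dataset (seed 42)."""
    return generate_dataset(SyntheticConfig())
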