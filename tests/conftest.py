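import numpy as np
import pytest

from eoesgc.similarity import DiseaseOntology, SimilarityMatrix


@pytest.fixture
def chain_ontology():
    """c -> p -> g with one disease on the chain tip."""
    return DiseaseOntology(
        terms={"c", "p", "g"},
        edges={("c", "p"), ("p", "g")},
        disease_terms={"D": {"c"}},
    )


@pytest.fixture
def diamond_ontology():
    """c -> {p1, p2} -> g."""
    return DiseaseOntology(
        terms={"c", "p1", "p2", "g"},
        edges={("c", "p1"), ("c", "p2"), ("p1", "g"), ("p2", "g")},
        disease_terms={"D": {"c"}},
    )


@pytest.fixture
def shared_parent_ontology():
    """Diseases A and B with terms a, b under a common parent P."""
    return DiseaseOntology(
        terms={"a", "b", "P"},
        edges={("a", "P"), ("b", "P")},
        disease_terms={"A": {"a"}, "B": {"b"}},
    )


@pytest.fixture
def toy_similarity():
    values = np.array(
        [
            [1.0, 0.4, 0.8],
            [0.4, 1.0, 0.3],
            [0.8, 0.3, 1.0],
        ]
    )
    return SimilarityMatrix(["d1", "d2", "d3"], values)


def random_dag_edges(rng, n_nodes):
    """Random DAG in topological order: node i may point at any j < i."""
    names = [f"t{i}" for i in range(n_nodes)]
    edges = set()
    for i in range(1, n_nodes):
        n_parents = rng.integers(1, min(i, 3) + 1)
        for p in rng.choice(i, size=n_parents, replace=False):
            edges.add((names[i], names[int(p)]))
    return names, edges
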