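import numpy as np
import pytest

from ontonorm.embeddings import EmbeddingStore
from ontonorm.ontology import Concept, OntologyGraph


@pytest.fixture
def chain_graph():
    """C is_a B is_a A."""
    return OntologyGraph(
        [
            Concept("A", "alpha"),
            Concept("B", "beta", parent_ids=["A"]),
            Concept("C", "gamma", parent_ids=["B"]),
        ]
    )


@pytest.fixture
def star_graph():
    """Root with three leaf children."""
    return OntologyGraph(
        [
            Concept("R", "root"),
            Concept("L1", "leaf one", parent_ids=["R"]),
            Concept("L2", "leaf two", parent_ids=["R"]),
            Concept("L3", "leaf three", parent_ids=["R"]),
        ]
    )


@pytest.fixture
def xy_store():
    """Toy 2-d store with orthogonal unit tokens x and y."""
    return EmbeddingStore(
        dim=2, vectors={"x": np.array([1.0, 0.0]), "y": np.array([0.0, 1.0])}
    )


def random_dag(rng: np.random.Generator, n_nodes: int) -> OntologyGraph:
    """Random is_a DAG: node i may take up to 3 parents among nodes < i."""
    concepts = [Concept("N000", "node 0")]
    for i in range(1, n_nodes):
        n_parents = int(rng.integers(0, min(i, 3) + 1))
        parents = sorted(
            f"N{int(p):03d}" for p in rng.choice(i, size=n_parents, replace=False)
        )
        concepts.append(Concept(f"N{i:03d}", f"node {i}", parent_ids=parents))
    return OntologyGraph(concepts)


def brute_force_ancestor_weights(graph: OntologyGraph, cid: str, s: float) -> dict:
    """Oracle: enumerate every is_a path explicitly; weight = max s**len."""
    weights: dict[str, float] = {}

    def walk(node: str, depth: int) -> None:
        w = s**depth
        if w > weights.get(node, 0.0):
            weights[node] = w
        for parent in graph.concepts[node].parent_ids:
            walk(parent, depth + 1)

    walk(cid, 0)
    return weights


def brute_force_wang(graph: OntologyGraph, c1: str, c2: str, s: float) -> float:
    t1 = brute_force_ancestor_weights(graph, c1, s)
    t2 = brute_force_ancestor_weights(graph, c2, s)
    shared = t1.keys() & t2.keys()
    return sum(t1[a] + t2[a] for a in shared) / (sum(t1.values()) + sum(t2.values()))
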