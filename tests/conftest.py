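import numpy as np
import pytest

from cpredictor3 import GoDag, small_worked_fixture


@pytest.fixture
def worked():
    """The fixed hand-checkable bundle (chain DAG, triangle+x graph, 0.25 pair)."""
    return small_worked_fixture()


def random_dag(rng: np.random.Generator, n_terms: int, edge_p: float = 0.4) -> GoDag:
    """A random weighted DAG with mixed is-a/part-of edges.

    Terms are ordered T0..T{n-1}; edges only run child(high index) ->
    parent(low index), which guarantees acyclicity.  Every non-root term gets
    at least one parent so ancestries are non-trivial.
    """
    terms = [f"T{i}" for i in range(n_terms)]
    edges = []
    for child_idx in range(1, n_terms):
        parents = [p for p in range(child_idx) if rng.random() < edge_p]
        if not parents:
            parents = [int(rng.integers(child_idx))]
        for parent_idx in parents:
            weight = 0.8 if rng.random() < 0.5 else 0.6
            edges.append((terms[child_idx], terms[parent_idx], weight))
    return GoDag.from_edges(edges, terms=terms)


def brute_force_contributions(dag: GoDag, term: str) -> dict[str, float]:
    """Independent oracle: S_term(t) as the max edge-weight product over all
    directed paths term -> ... -> t, by exhaustive path enumeration."""
    best = {term: 1.0}

    def walk(node: str, product: float) -> None:
        for parent in dag.parents(node):
            value = product * dag.edge_weight(node, parent)
            if value > best.get(parent, 0.0):
                best[parent] = value
            walk(parent, value)

    walk(term, 1.0)
    return best
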