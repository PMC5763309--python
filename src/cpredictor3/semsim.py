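"""Wang-method GO semantic similarity.

Each term A induces a sub-DAG of its ancestors; an ancestor t contributes

    S_A(t) = max over directed paths t <- ... <- A of the product of edge weights

with S_A(A) = 1 (equivalently the recursive rule S_A(t) = max_{t' in
children(t) within the ancestry} w_e * S_A(t')).  The semantic value SV(A) is
the sum of contributions, and two terms compare through their shared
ancestors:

    S_GO(A, B) = sum_{t in T_A n T_B} (S_A(t) + S_B(t)) / (SV(A) + SV(B))

Protein similarity averages best-match term similarities in both directions.
The similarity of a protein pair is 1 exactly when their annotation term sets
coincide, which is what the downstream spectral clustering assumes of its
affinity diagonal.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import GoDag

__all__ = [
    "semantic_contributions",
    "semantic_value",
    "term_similarity",
    "protein_similarity",
    "similarity_matrix",
    "SemanticCache",
]


def semantic_contributions(dag: GoDag, term: str) -> dict[str, float]:
    """Map each ancestor-or-self t of ``term`` to its contribution S_term(t).

    Computed by dynamic programming upward from ``term``: a parent's
    contribution is the best child's contribution times the edge weight, so
    every value lies in (0, 1] and S_term(term) = 1.
    """
    if term not in dag:
        raise KeyError(f"unknown term {term!r}")
    contributions: dict[str, float] = {term: 1.0}
    # breadth-first over parents; re-relax when a better path arrives later
    frontier = [term]
    while frontier:
        next_frontier: list[str] = []
        for child in frontier:
            s_child = contributions[child]
            for parent in dag.parents(child):
                candidate = dag.edge_weight(child, parent) * s_child
                if candidate > contributions.get(parent, 0.0):
                    contributions[parent] = candidate
                    next_frontier.append(parent)
        frontier = next_frontier
    return contributions


def semantic_value(dag: GoDag, term: str) -> float:
    """SV(term): the sum of contributions over the term's ancestry (>= 1)."""
    return float(sum(semantic_contributions(dag, term).values()))


class SemanticCache:
    """Memoises per-term S-value maps so a similarity matrix touches each
    distinct term once."""

    def __init__(self, dag: GoDag) -> None:
        self.dag = dag
        self._maps: dict[str, dict[str, float]] = {}
        self._sv: dict[str, float] = {}

    def contributions(self, term: str) -> dict[str, float]:
        if term not in self._maps:
            smap = semantic_contributions(self.dag, term)
            self._maps[term] = smap
            self._sv[term] = sum(smap.values())
        return self._maps[term]

    def sv(self, term: str) -> float:
        self.contributions(term)
        return self._sv[term]


def term_similarity(
    dag: GoDag,
    a: str,
    b: str,
    numerator: str = "wang",
    cache: SemanticCache | None = None,
) -> float:
    """Semantic similarity S_GO(a, b) in [0, 1].

    ``numerator`` selects the shared-ancestor aggregate: "wang" (default) sums
    S_a(t) + S_b(t), which normalises self-similarity to 1; "literal" sums
    SV(t) instead, kept for audit of the alternative printed formulation.
    """
    if numerator not in ("wang", "literal"):
        raise ValueError(f"numerator must be 'wang' or 'literal', got {numerator!r}")
    if cache is None:
        cache = SemanticCache(dag)
    sa = cache.contributions(a)
    sb = cache.contributions(b)
    shared = sa.keys() & sb.keys()
    if not shared:
        return 0.0
    if numerator == "wang":
        num = sum(sa[t] + sb[t] for t in shared)
    else:
        num = sum(cache.sv(t) for t in shared)
    return num / (cache.sv(a) + cache.sv(b))


def protein_similarity(
    dag: GoDag,
    annotations: Mapping[str, Iterable[str]],
    p1: str,
    p2: str,
    numerator: str = "wang",
    cache: SemanticCache | None = None,
) -> float:
    """Best-match average similarity of two proteins' annotation term sets.

    Sim(P1, P2) = (sum_i max_j S_GO(go_1i, go_2j)
                   + sum_j max_i S_GO(go_2j, go_1i)) / (m + n).
    """
    terms1 = sorted(set(annotations.get(p1, ())))
    terms2 = sorted(set(annotations.get(p2, ())))
    if not terms1 or not terms2:
        missing = p1 if not terms1 else p2
        raise KeyError(f"protein {missing!r} has no annotation")
    if cache is None:
        cache = SemanticCache(dag)
    pair = np.array(
        [[term_similarity(dag, t1, t2, numerator, cache) for t2 in terms2] for t1 in terms1]
    )
    total = pair.max(axis=1).sum() + pair.max(axis=0).sum()
    return float(total / (len(terms1) + len(terms2)))


def similarity_matrix(
    dag: GoDag,
    annotations: Mapping[str, Iterable[str]],
    proteins: list[str] | None = None,
    numerator: str = "wang",
) -> pd.DataFrame:
    """Symmetric protein x protein similarity matrix with unit diagonal.

    ``proteins`` defaults to all annotated proteins in sorted order; every
    listed protein must be annotated.  S-value maps are computed once per
    distinct term.
    """
    if proteins is None:
        proteins = sorted(annotations)
    cache = SemanticCache(dag)
    n = len(proteins)
    matrix = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            value = protein_similarity(
                dag, annotations, proteins[i], proteins[j], numerator, cache
            )
            matrix[i, j] = matrix[j, i] = value
    return pd.DataFrame(matrix, index=proteins, columns=proteins)
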