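"""Spectral clustering of the protein functional-similarity matrix.

Normalised spectral clustering in the Ng-Jordan-Weiss form: the bounded
similarity matrix is used directly as the affinity, the top-K eigenvectors of
D^{-1/2} A D^{-1/2} form the embedding, rows are normalised to the unit
sphere, and a seeded k-means assigns clusters.  When the affinity graph
splits into at least K connected components the components are grouped
directly (each is a zero-cut cluster), which sidesteps the arbitrary
eigenbasis of a degenerate null space.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.linalg import eigh
from sklearn.cluster import KMeans

from .io import IntegrityError

__all__ = ["FunctionClusters", "spectral_clusters"]


@dataclass
class FunctionClusters:
    """A disjoint partition of the clustered proteins into at most K groups."""

    clusters: list[set[str]]
    k: int
    seed: int = 0

    def __post_init__(self) -> None:
        self.clusters = [set(c) for c in self.clusters]

    def nonempty(self) -> list[set[str]]:
        return [c for c in self.clusters if c]

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.clusters:
            out |= c
        return out

    def as_sets(self) -> set[frozenset[str]]:
        return {frozenset(c) for c in self.clusters if c}


def _affinity_components(sim: np.ndarray, proteins: list[str]) -> list[list[int]]:
    graph = nx.Graph()
    graph.add_nodes_from(range(len(proteins)))
    rows, cols = np.nonzero(np.triu(sim, k=1) > 0)
    graph.add_edges_from(zip(rows.tolist(), cols.tolist()))
    comps = [sorted(c) for c in nx.connected_components(graph)]
    # deterministic order: big components first, ties by smallest member label
    comps.sort(key=lambda c: (-len(c), min(proteins[i] for i in c)))
    return comps


def spectral_clusters(sim: pd.DataFrame, k: int, seed: int = 0) -> FunctionClusters:
    """Partition the proteins of ``sim`` into at most ``k`` clusters.

    ``sim`` must be a square labelled DataFrame, symmetric with unit
    diagonal.  The result is deterministic for a fixed (sim, k, seed).
    """
    proteins = list(sim.index)
    n = len(proteins)
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of proteins ({n})")
    matrix = sim.to_numpy(dtype=float)
    if matrix.shape[0] != matrix.shape[1] or list(sim.columns) != proteins:
        raise IntegrityError("similarity matrix must be square with matching labels")
    if not np.allclose(matrix, matrix.T, atol=1e-10):
        raise IntegrityError("similarity matrix must be symmetric")
    if np.any(matrix < -1e-12) or np.any(matrix > 1 + 1e-12):
        raise IntegrityError("similarity values must lie in [0, 1]")

    if k == 1:
        return FunctionClusters([set(proteins)], k=k, seed=seed)

    comps = _affinity_components(matrix, proteins)
    if len(comps) >= k:
        # zero-cut partition exists: pack whole components into k groups,
        # always adding to the currently smallest group
        groups: list[list[int]] = [[] for _ in range(k)]
        for comp in comps:
            target = min(range(k), key=lambda g: (len(groups[g]), g))
            groups[target].extend(comp)
        clusters = [{proteins[i] for i in group} for group in groups]
        return FunctionClusters(clusters, k=k, seed=seed)

    degrees = matrix.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degrees)
    normalised = matrix * inv_sqrt[:, None] * inv_sqrt[None, :]
    # top-k eigenvectors of the normalised affinity = bottom of L_sym
    _vals, vecs = eigh(normalised, subset_by_index=(n - k, n - 1))
    # canonical sign: make each eigenvector sum non-negative (falls back to
    # the largest-magnitude entry when the sum is ~0) so permuting the input
    # permutes the embedding rows rather than flipping them
    for col in range(vecs.shape[1]):
        total = vecs[:, col].sum()
        if abs(total) < 1e-9:
            total = vecs[np.argmax(np.abs(vecs[:, col])), col]
        if total < 0:
            vecs[:, col] = -vecs[:, col]
    norms = np.linalg.norm(vecs, axis=1)
    norms[norms == 0] = 1.0
    embedding = vecs / norms[:, None]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed & 0x7FFFFFFF)
    labels = km.fit_predict(embedding)
    clusters = [set() for _ in range(k)]
    for idx, label in enumerate(labels):
        clusters[label].add(proteins[idx])
    return FunctionClusters(clusters, k=k, seed=seed)
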