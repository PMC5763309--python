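"""Seeded synthetic instances for every pipeline stage.

The generator emulates the structural assumptions behind the method: proteins
of a complex interact densely, share function, and are active over the same
time window.  A planted complex is an Erdos-Renyi-dense subgraph over a
sparse background network (planted members also take part in background
edges, giving realistic false-positive attachments); each complex owns a
distinct signature leaf term in a small is-a/part-of tree and its members are
annotated to that leaf (or, with probability 1 - coherence, to a sibling
leaf); expression rows are baseline noise plus a pulse across the complex's
contiguous active window.  Background proteins carry no annotation — they can
only join a predicted complex through expansion, exactly as unannotated
proteins would in real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from types import SimpleNamespace

import networkx as nx
import numpy as np
import pandas as pd

from .io import ComplexSet, GoDag, write_complexes

__all__ = ["SyntheticSpec", "SyntheticInstance", "generate", "small_worked_fixture", "write_instance"]


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic study instance.

    Defaults give 10 planted complexes of 4-8 proteins (dense at 0.9) in a
    100-node background at edge probability 0.01, twelve time points (one
    metabolic-cycle-like sweep), a pulse of height 1.0 over noise of SD 0.2
    (signal-to-noise 5), and perfectly coherent annotations.
    """

    n_complexes: int = 10
    size_range: tuple[int, int] = (4, 8)
    within_p: float = 0.9
    n_background: int = 100
    background_p: float = 0.01
    n_timepoints: int = 12
    window_len: int = 4
    baseline: float = 5.0
    pulse_height: float = 1.0
    noise_sd: float = 0.2
    coherence: float = 1.0
    dag_depth: int = 3
    dag_branching: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("within_p", "background_p", "coherence"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.size_range[0] < 3 or self.size_range[1] < self.size_range[0]:
            raise ValueError(f"invalid size range {self.size_range} (minimum size 3)")
        if self.pulse_height <= 0:
            raise ValueError("pulse height must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")
        if not 1 <= self.window_len <= self.n_timepoints:
            raise ValueError("window length must be in [1, n_timepoints]")
        if self.dag_branching**self.dag_depth < self.n_complexes:
            raise ValueError(
                "DAG too small: need at least one signature leaf per complex "
                f"({self.dag_branching}^{self.dag_depth} < {self.n_complexes})"
            )


@dataclass
class SyntheticInstance:
    """A generated bundle: network, expression, ontology, annotations, truth."""

    ppi: nx.Graph
    expr: pd.DataFrame
    dag: GoDag
    annotations: dict[str, set[str]]
    truth: ComplexSet
    spec: SyntheticSpec


def _make_dag(rng: np.random.Generator, depth: int, branching: int) -> tuple[GoDag, list[str]]:
    """A rooted tree of GO-like terms with randomly typed edges; returns the
    DAG and its leaves."""
    edges: list[tuple[str, str, float]] = []
    level_nodes = ["GO:R"]
    counter = 0
    for _level in range(depth):
        next_level = []
        for parent in level_nodes:
            for _ in range(branching):
                counter += 1
                child = f"GO:{counter:07d}"
                weight = 0.8 if rng.random() < 0.7 else 0.6  # is-a vs part-of
                edges.append((child, parent, weight))
                next_level.append(child)
        level_nodes = next_level
    return GoDag.from_edges(edges, terms=["GO:R"]), level_nodes


def generate(spec: SyntheticSpec) -> SyntheticInstance:
    """Generate a full instance, deterministic for a given spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)

    sizes = rng.integers(spec.size_range[0], spec.size_range[1] + 1, spec.n_complexes)
    n_members = int(sizes.sum())
    n_total = n_members + spec.n_background
    proteins = [f"P{idx:04d}" for idx in range(1, n_total + 1)]

    complexes: list[frozenset[str]] = []
    cursor = 0
    member_slices: list[list[str]] = []
    for size in sizes:
        members = proteins[cursor : cursor + int(size)]
        cursor += int(size)
        member_slices.append(members)
        complexes.append(frozenset(members))
    truth = ComplexSet(complexes, label="planted")

    # network: dense within each planted complex, sparse elsewhere
    ppi = nx.Graph()
    ppi.add_nodes_from(proteins)
    within_pairs: set[frozenset[str]] = set()
    for members in member_slices:
        for a, b in combinations(members, 2):
            within_pairs.add(frozenset((a, b)))
            if rng.random() < spec.within_p:
                ppi.add_edge(a, b)
    if spec.background_p > 0:
        for a, b in combinations(proteins, 2):
            if frozenset((a, b)) in within_pairs:
                continue
            if rng.random() < spec.background_p:
                ppi.add_edge(a, b)

    # ontology and per-complex signature annotations
    dag, leaves = _make_dag(rng, spec.dag_depth, spec.dag_branching)
    signature = list(rng.choice(leaves, size=spec.n_complexes, replace=False))
    annotations: dict[str, set[str]] = {}
    for members, leaf in zip(member_slices, signature):
        siblings = [s for s in dag.children(dag.parents(leaf)[0]) if s != leaf]
        for protein in members:
            if rng.random() < spec.coherence or not siblings:
                term = leaf
            else:
                term = siblings[int(rng.integers(len(siblings)))]
            annotations.setdefault(protein, set()).add(term)

    # expression: baseline noise everywhere, a pulse over each complex window
    values = spec.baseline + spec.noise_sd * rng.standard_normal(
        (n_total, spec.n_timepoints)
    )
    starts = rng.integers(0, spec.n_timepoints - spec.window_len + 1, spec.n_complexes)
    row_of = {p: i for i, p in enumerate(proteins)}
    for members, start in zip(member_slices, starts):
        for protein in members:
            values[row_of[protein], start : start + spec.window_len] += spec.pulse_height
    expr = pd.DataFrame(
        values,
        index=proteins,
        columns=[f"t{k}" for k in range(1, spec.n_timepoints + 1)],
    )
    return SyntheticInstance(ppi, expr, dag, annotations, truth, spec)


def small_worked_fixture() -> SimpleNamespace:
    """The fixed hand-checkable bundle used across the documentation.

    Contains the three-term is-a chain A <- B <- C (SV(C) = 1 + 0.8 + 0.64 =
    2.44), a triangle {a, b, c} with an extra node x attached to a and b (the
    expansion case: 2 edges vs threshold alpha*3), and the affinity pair
    P = {a, b}, R = {b, c} whose score is 1/(2*2) = 0.25.
    """
    dag = GoDag.from_edges([("C", "B", 0.8), ("B", "A", 0.8)])
    ppi = nx.Graph()
    ppi.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("x", "a"), ("x", "b")])
    return SimpleNamespace(
        dag=dag,
        chain_terms=("A", "B", "C"),
        ppi=ppi,
        seed_complex=frozenset({"a", "b", "c"}),
        expansion_node="x",
        affinity_pair=(frozenset({"a", "b"}), frozenset({"b", "c"})),
    )


def write_instance(instance: SyntheticInstance, outdir: str | Path) -> dict[str, Path]:
    """Write the five files of an instance in the pipeline's input formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ppi": outdir / "ppi.tsv",
        "expr": outdir / "expression.tsv",
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "complexes": outdir / "complexes.txt",
    }
    with open(paths["ppi"], "w", encoding="utf-8") as handle:
        for a, b in sorted(tuple(sorted(e)) for e in instance.ppi.edges):
            handle.write(f"{a}\t{b}\n")
        for node in sorted(nx.isolates(instance.ppi)):
            handle.write(f"{node}\t{node}\n")  # read back as an isolated node
    instance.expr.to_csv(paths["expr"], sep="\t")
    _write_obo(instance.dag, paths["obo"])
    with open(paths["annotations"], "w", encoding="utf-8") as handle:
        for protein in sorted(instance.annotations):
            for term in sorted(instance.annotations[protein]):
                handle.write(f"{protein}\t{term}\n")
    write_complexes(instance.truth, paths["complexes"])
    return paths


def _write_obo(dag: GoDag, path: Path) -> None:
    """Minimal OBO 1.2 serialisation of a synthetic DAG (BP namespace)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("format-version: 1.2\n")
        for term in sorted(dag.terms):
            handle.write(f"\n[Term]\nid: {term}\nname: {term}\n")
            handle.write("namespace: biological_process\n")
            for parent in sorted(dag.parents(term)):
                if dag.edge_weight(term, parent) >= 0.8:
                    handle.write(f"is_a: {parent} ! {parent}\n")
                else:
                    handle.write(f"relationship: part_of {parent} ! {parent}\n")
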