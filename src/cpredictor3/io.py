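"""Readers and writers for the external file formats.

Protein IDs are case-sensitive opaque strings everywhere; joins across files
are exact string matches.  Lines starting with ``#`` or ``%`` are treated as
comments in all TSV dialects.

In-memory containers:

* PPI network        -> :class:`networkx.Graph` (undirected, simple, no self-loops)
* expression matrix  -> :class:`pandas.DataFrame` (rows = proteins, columns = time points)
* GO DAG             -> :class:`GoDag` (child->parent DiGraph with per-edge weights)
* annotations        -> ``dict[str, set[str]]`` (protein -> BP term IDs)
* complex sets       -> :class:`ComplexSet`
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

#: edge weights by relationship type: 0.8 for is-a, 0.6 for part-of
DEFAULT_RELATION_WEIGHTS: dict[str, float] = {"is_a": 0.8, "part_of": 0.6}

_COMMENT_PREFIXES = ("#", "%")


class ParseError(ValueError):
    """A line of an input file could not be interpreted."""


class IntegrityError(ValueError):
    """An input violated a structural requirement (e.g. a cyclic ontology)."""


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    """Yield (1-based line number, stripped line) skipping blanks and comments."""
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith(_COMMENT_PREFIXES):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# PPI network
# ---------------------------------------------------------------------------

def read_ppi_edgelist(path: str | Path) -> nx.Graph:
    """Read an undirected PPI network from a TSV edge list.

    Each non-comment line holds at least two whitespace-separated protein IDs;
    extra columns (confidence scores etc.) are ignored because the method runs
    on an unweighted static network.  Duplicate edges are collapsed and
    self-loops are dropped (with a logged count).
    """
    graph = nx.Graph()
    self_loops = 0
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected two protein IDs, got {line!r}")
        a, b = fields[0], fields[1]
        if a == b:
            self_loops += 1
            graph.add_node(a)
            continue
        graph.add_edge(a, b)
    if self_loops:
        logger.info("dropped %d self-loop(s) while reading %s", self_loops, path)
    if graph.number_of_nodes() == 0:
        raise ParseError(f"{path}: empty network (no edges or nodes found)")
    return graph


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path: str | Path,
    cycles: int = 1,
    points_per_cycle: int | None = None,
) -> pd.DataFrame:
    """Read a gene-expression time course, optionally averaging repeated cycles.

    The file is a TSV with a header row of time labels and one protein per row.
    When the experiment repeats a cycle of ``points_per_cycle`` measurements
    ``cycles`` times (e.g. three successive metabolic cycles of 12 points), the
    returned matrix has exactly ``points_per_cycle`` columns where column *k*
    is the arithmetic mean of columns ``k, k + points_per_cycle, ...`` —
    averaging over cycles damps measurement noise before thresholding.
    """
    kept = []
    with open(path, encoding="utf-8") as handle:
        for raw in handle:
            stripped = raw.strip()
            if not stripped or stripped.startswith(_COMMENT_PREFIXES):
                continue
            kept.append(raw)
    if not kept:
        raise ParseError(f"{path}: empty expression file")
    try:
        frame = pd.read_csv(_stdio.StringIO("".join(kept)), sep="\t", index_col=0)
        values = frame.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric expression value ({exc})") from exc
    if values.index.has_duplicates:
        dupes = values.index[values.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate protein IDs {dupes}")
    if not values.notna().all().all():
        raise ParseError(f"{path}: missing expression values")

    if points_per_cycle is None:
        if cycles != 1:
            raise ValueError("points_per_cycle is required when cycles > 1")
        return values
    n_cols = values.shape[1]
    if n_cols != cycles * points_per_cycle:
        raise ParseError(
            f"{path}: expected {cycles} x {points_per_cycle} = "
            f"{cycles * points_per_cycle} columns, found {n_cols}"
        )
    if cycles == 1:
        return values
    blocks = [
        values.iloc[:, c * points_per_cycle : (c + 1) * points_per_cycle].to_numpy()
        for c in range(cycles)
    ]
    averaged = sum(blocks) / cycles
    columns = list(values.columns[:points_per_cycle])
    return pd.DataFrame(averaged, index=values.index, columns=columns)


# ---------------------------------------------------------------------------
# GO DAG
# ---------------------------------------------------------------------------

@dataclass
class GoDag:
    """A Gene Ontology fragment as a weighted DAG.

    ``graph`` stores one directed edge per child->parent relationship, with a
    ``weight`` attribute carrying the semantic-contribution factor of that
    relationship type (is-a 0.8, part-of 0.6 by default).
    """

    graph: nx.DiGraph

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def roots(self) -> set[str]:
        return {t for t in self.graph if self.graph.out_degree(t) == 0}

    def parents(self, term: str) -> list[str]:
        return list(self.graph.successors(term))

    def children(self, term: str) -> list[str]:
        return list(self.graph.predecessors(term))

    def edge_weight(self, child: str, parent: str) -> float:
        return self.graph.edges[child, parent]["weight"]

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str, float]],
        terms: Iterable[str] = (),
    ) -> "GoDag":
        """Build a DAG from (child, parent, weight) triples; used by the
        synthetic generator and tests."""
        graph = nx.DiGraph()
        graph.add_nodes_from(terms)
        for child, parent, weight in edges:
            if not 0.0 < weight < 1.0:
                raise ValueError(f"edge weight must be in (0, 1), got {weight}")
            graph.add_edge(child, parent, weight=weight)
        if not nx.is_directed_acyclic_graph(graph):
            raise IntegrityError("term graph contains a cycle")
        return cls(graph)


def read_obo(
    path: str | Path,
    aspect: str = "biological_process",
    weights: Mapping[str, float] | None = None,
) -> GoDag:
    """Load an OBO ontology, keeping one namespace and weighted relationships.

    Only terms of ``aspect`` are retained (the method uses the biological
    process branch).  Relationship types absent from ``weights`` (regulates,
    occurs_in, ...) are dropped with a logged count; the legacy ``part-of``
    spelling is treated as ``part_of``.  Obsolete terms are excluded.
    """
    if weights is None:
        weights = DEFAULT_RELATION_WEIGHTS
    weights = {key.replace("-", "_"): value for key, value in weights.items()}
    raw = obonet.read_obo(path)  # MultiDiGraph, child -> parent, key = relation

    graph = nx.DiGraph()
    for term, data in raw.nodes(data=True):
        if data.get("namespace") == aspect:
            graph.add_node(term)
    dropped_rel = 0
    for child, parent, relation in raw.edges(keys=True):
        if child not in graph or parent not in graph:
            continue
        relation = relation.replace("-", "_")
        if relation not in weights:
            dropped_rel += 1
            continue
        graph.add_edge(child, parent, weight=weights[relation])
    if dropped_rel:
        logger.info("dropped %d edge(s) with unweighted relationship types", dropped_rel)
    if not nx.is_directed_acyclic_graph(graph):
        raise IntegrityError(f"{path}: ontology graph is cyclic after filtering")
    return GoDag(graph)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def read_annotations(path: str | Path, dag: GoDag) -> dict[str, set[str]]:
    """Read protein->GO-term annotations from a GAF 2.x file or 2-column TSV.

    GAF rows with a NOT qualifier are dropped, as are annotations to terms not
    present in ``dag`` (e.g. other namespaces); proteins left with no terms do
    not appear in the result.
    """
    mapping: dict[str, set[str]] = {}
    dropped_terms = 0
    dropped_not = 0
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("!",) + _COMMENT_PREFIXES):
                continue
            fields = line.split("\t")
            if len(fields) >= 15:  # GAF 2.x
                protein, qualifier, term = fields[1], fields[3], fields[4]
                if "NOT" in qualifier.split("|"):
                    dropped_not += 1
                    continue
            elif len(fields) >= 2:
                protein, term = fields[0].strip(), fields[1].strip()
            else:
                raise ParseError(
                    f"{path}:{lineno}: expected GAF or 2-column TSV row, got {line!r}"
                )
            if not protein or not term:
                raise ParseError(f"{path}:{lineno}: empty protein or term field")
            if term not in dag:
                dropped_terms += 1
                continue
            mapping.setdefault(protein, set()).add(term)
    if dropped_terms:
        logger.info("dropped %d annotation(s) to terms outside the DAG", dropped_terms)
    if dropped_not:
        logger.info("dropped %d NOT-qualified annotation(s)", dropped_not)
    return mapping


# ---------------------------------------------------------------------------
# Complex sets
# ---------------------------------------------------------------------------

@dataclass
class ComplexSet:
    """An ordered list of protein complexes (non-empty protein-ID sets)."""

    complexes: list[frozenset[str]] = field(default_factory=list)
    label: str | None = None

    def __post_init__(self) -> None:
        self.complexes = [frozenset(c) for c in self.complexes]
        if any(not c for c in self.complexes):
            raise ValueError("complexes must be non-empty")

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self):
        return iter(self.complexes)

    def proteins(self) -> set[str]:
        out: set[str] = set()
        for c in self.complexes:
            out |= c
        return out

    def sizes(self) -> list[int]:
        return [len(c) for c in self.complexes]

    def deduplicated(self) -> "ComplexSet":
        seen: set[frozenset[str]] = set()
        unique: list[frozenset[str]] = []
        for c in self.complexes:
            if c not in seen:
                seen.add(c)
                unique.append(c)
        if len(unique) < len(self.complexes):
            logger.info(
                "collapsed %d duplicate complex(es)", len(self.complexes) - len(unique)
            )
        return ComplexSet(unique, label=self.label)

    def sorted(self) -> "ComplexSet":
        """Canonical order: by sorted member tuple (gives reproducible files)."""
        return ComplexSet(
            sorted(self.complexes, key=lambda c: tuple(sorted(c))), label=self.label
        )


def read_complexes(path: str | Path, label: str | None = None) -> ComplexSet:
    """Read a line-per-complex file (MIPS/CYC2008 style, whitespace-separated)."""
    complexes: list[frozenset[str]] = []
    for _lineno, line in _data_lines(path):
        members = frozenset(line.split())
        complexes.append(members)
    return ComplexSet(complexes, label=label)


def write_complexes(cs: ComplexSet, path: str | Path) -> None:
    """Write one complex per line, members sorted and tab-separated."""
    with open(path, "w", encoding="utf-8") as handle:
        for c in cs:
            handle.write("\t".join(sorted(c)) + "\n")
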