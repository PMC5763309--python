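"""Candidate-complex generation: intersect, extract, expand, merge, predict.

The end-to-end flow mirrors the method's six steps: detect per-time-point
active proteins, cluster annotated proteins by functional similarity,
intersect the two groupings (APC_ij = AP_i n PC_j), take connected subgraphs
induced on the static PPI network as candidates, grow each candidate by
admitting well-connected neighbours, and merge heavily overlapping candidates
into the final prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import networkx as nx
import pandas as pd

from .activity import detect_active_sets
from .clustering import FunctionClusters, spectral_clusters
from .io import ComplexSet, GoDag
from .semsim import similarity_matrix

logger = logging.getLogger(__name__)

#: slack for threshold comparisons so exact rational equalities (3 >= 0.6*5)
#: survive binary floating point
_EPS = 1e-9

__all__ = [
    "CandidateComplex",
    "PipelineParams",
    "intersect_active_clusters",
    "extract_candidates",
    "expand_candidate",
    "merge_candidates",
    "overlap_score",
    "predict",
]


@dataclass(frozen=True)
class CandidateComplex:
    """A protein set with its provenance (time point, cluster) and stage tag."""

    members: frozenset[str]
    provenance: tuple[tuple[int, int], ...] = ()
    stage: str = "extracted"

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class PipelineParams:
    """Tunable parameters of the prediction pipeline.

    beta      stringency of the three-sigma activity threshold (0 = row mean)
    k         number of functional clusters
    alpha     expansion threshold: a neighbour joins when its edges into the
              candidate reach alpha * |candidate|  (default 0.6)
    gamma     merge threshold on the overlap score |A n B| / |A u B| (default 0.8)
    min_size  smallest complex reported (default 3: size-2 predictions are
              discarded because any size-2 pair sharing one protein already
              scores 0.25 >= 0.2 and would match references spuriously)
    """

    beta: float = 0.0
    k: int = 30
    alpha: float = 0.6
    gamma: float = 0.8
    seed: int = 0
    min_size: int = 3
    sd_mode: str = "population"
    s_go_numerator: str = "wang"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.beta < 0:
            raise ValueError(f"beta must be non-negative, got {self.beta}")


#: parameter presets from tuning on the published yeast benchmark networks
PRESETS: dict[str, PipelineParams] = {
    "collins": PipelineParams(beta=0.0, k=30),
    "krogan": PipelineParams(beta=0.0, k=35),
    "wiphi": PipelineParams(beta=1.0, k=17),
}


def intersect_active_clusters(
    active_sets: list[set[str]], clusters: FunctionClusters
) -> dict[tuple[int, int], set[str]]:
    """APC_ij = AP_i n PC_j for every time point i and cluster j (1-based).

    Empty intersections are retained; extraction drops them for free.
    """
    return {
        (i, j): active & cluster
        for i, active in enumerate(active_sets, start=1)
        for j, cluster in enumerate(clusters.clusters, start=1)
    }


def extract_candidates(
    apc: set[str], ppi: nx.Graph, provenance: tuple[int, int] | None = None
) -> list[CandidateComplex]:
    """Connected components (size >= 2) of the subgraph induced by ``apc``."""
    present = apc & set(ppi.nodes)
    if not present:
        return []
    prov = (provenance,) if provenance is not None else ()
    sub = ppi.subgraph(present)
    out = []
    for component in nx.connected_components(sub):
        if len(component) > 1:
            out.append(CandidateComplex(frozenset(component), prov, "extracted"))
    out.sort(key=lambda c: tuple(sorted(c.members)))
    return out


def expand_candidate(
    cand: CandidateComplex, ppi: nx.Graph, alpha: float
) -> CandidateComplex:
    """Grow a candidate by absorbing strongly attached neighbours.

    Each pass evaluates every current neighbour p against the candidate as it
    stood at the start of the pass — p joins when it has at least
    alpha * |V_c| interactions into the candidate — then admits all qualifying
    neighbours simultaneously; passes repeat until none qualifies.  With
    alpha=0 this absorbs the whole connected component; with alpha=1 a
    neighbour would need an edge to every member.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    members = set(cand.members)
    while True:
        threshold = alpha * len(members) - _EPS
        frontier = {
            neighbour
            for member in members
            if member in ppi
            for neighbour in ppi.neighbors(member)
            if neighbour not in members
        }
        admitted = {
            p
            for p in frontier
            if sum(1 for q in ppi.neighbors(p) if q in members) >= threshold
        }
        if not admitted:
            break
        members |= admitted
    if members == set(cand.members):
        return replace(cand, stage="expanded")
    return CandidateComplex(frozenset(members), cand.provenance, "expanded")


def overlap_score(a: frozenset[str] | set[str], b: frozenset[str] | set[str]) -> float:
    """Jaccard overlap |A n B| / |A u B| used for the merge decision."""
    if not a or not b:
        raise ValueError("overlap score is undefined for empty sets")
    return len(set(a) & set(b)) / len(set(a) | set(b))


def _dedup(cands: list[CandidateComplex]) -> list[CandidateComplex]:
    """Collapse identical member sets, concatenating provenance."""
    by_members: dict[frozenset[str], CandidateComplex] = {}
    order: list[frozenset[str]] = []
    for cand in cands:
        if cand.members in by_members:
            prev = by_members[cand.members]
            by_members[cand.members] = replace(
                prev, provenance=prev.provenance + cand.provenance
            )
        else:
            by_members[cand.members] = cand
            order.append(cand.members)
    return [by_members[m] for m in order]


def merge_candidates(cands: list[CandidateComplex], gamma: float) -> ComplexSet:
    """Merge overlapping candidates until no pair overlaps at >= gamma.

    Exact duplicates are collapsed first.  Then the highest-overlap pair is
    repeatedly replaced by its union; ties are broken towards the smaller
    combined size, then the lexicographically smallest union, making the
    outcome independent of input order.  Every union strictly reduces the
    candidate count, so the loop terminates.
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must be in [0, 1], got {gamma}")
    pool = [c.members for c in _dedup(cands)]
    while len(pool) > 1:
        best = None
        best_key = None
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                score = overlap_score(pool[i], pool[j])
                if score < gamma - _EPS:
                    continue
                union = pool[i] | pool[j]
                key = (-score, len(union), tuple(sorted(union)))
                if best_key is None or key < best_key:
                    best_key = key
                    best = (i, j, union)
        if best is None:
            break
        i, j, union = best
        pool = [m for idx, m in enumerate(pool) if idx not in (i, j)]
        pool.append(union)
    # union of two overlapping sets may duplicate an existing member set
    seen: set[frozenset[str]] = set()
    unique = [m for m in pool if not (m in seen or seen.add(m))]
    return ComplexSet(unique, label="merged").sorted()


def predict(
    ppi: nx.Graph,
    expr: pd.DataFrame,
    dag: GoDag,
    annotations: dict[str, set[str]],
    params: PipelineParams | None = None,
    return_details: bool = False,
):
    """Run the full pipeline and return the predicted ComplexSet.

    Only annotated proteins enter clustering (functional similarity is
    undefined without annotations); unannotated proteins can still be
    recruited during expansion, which walks the full static network.  The
    output is deterministic for fixed inputs and seed and is returned in
    canonical sorted order.  With ``return_details=True`` a stage-by-stage
    count dictionary is returned alongside.
    """
    if params is None:
        params = PipelineParams()
    active_sets = detect_active_sets(expr, params.beta, params.sd_mode)
    sim = similarity_matrix(dag, annotations, numerator=params.s_go_numerator)
    k = min(params.k, len(sim))
    if k < params.k:
        logger.info("reducing k from %d to %d annotated proteins", params.k, k)
    clusters = spectral_clusters(sim, k, params.seed)
    apc = intersect_active_clusters(active_sets, clusters)

    extracted: list[CandidateComplex] = []
    for (i, j), members in sorted(apc.items()):
        extracted.extend(extract_candidates(members, ppi, (i, j)))
    deduped = _dedup(extracted)
    expanded = [expand_candidate(c, ppi, params.alpha) for c in deduped]
    merged = merge_candidates(expanded, params.gamma)
    final = ComplexSet(
        [c for c in merged if len(c) >= params.min_size], label="predicted"
    ).sorted()

    counts = {
        "active_per_timepoint": [len(s) for s in active_sets],
        "annotated_proteins": len(sim),
        "clusters_nonempty": len(clusters.nonempty()),
        "candidates_extracted": len(extracted),
        "candidates_unique": len(deduped),
        "candidates_expanded": len(expanded),
        "complexes_merged": len(merged),
        "complexes_final": len(final),
    }
    for stage, count in counts.items():
        logger.info("%s: %s", stage, count)
    if not len(final):
        logger.info("prediction is empty")
    if return_details:
        return final, counts
    return final
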