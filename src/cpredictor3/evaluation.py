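"""Scoring predictions against a reference complex catalogue.

A predicted complex P and a reference complex R match when their affinity
score AS(P, R) = |P n R|^2 / (|P| * |R|) reaches 0.2.  Matching is
one-to-many in both directions: N_p predicted complexes match some reference,
N_r references are recovered by some prediction, and

    recall = N_r / |RS|,  precision = N_p / |PS|,  F1 = 2rp / (r + p).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx

from .io import ComplexSet

logger = logging.getLogger(__name__)

#: affinity level at which a prediction and a reference count as matched
DEFAULT_MATCH_THRESHOLD = 0.2

__all__ = [
    "EvaluationReport",
    "affinity_score",
    "evaluate",
    "size_distribution",
    "overlap_ratio",
]


def affinity_score(p: frozenset[str] | set[str], r: frozenset[str] | set[str]) -> float:
    """AS(P, R) = |P n R|^2 / (|P| * |R|); symmetric, in [0, 1]."""
    p, r = set(p), set(r)
    if not p or not r:
        raise ValueError("affinity score is undefined for empty complexes")
    inter = len(p & r)
    return inter * inter / (len(p) * len(r))


def size_distribution(ps: ComplexSet) -> dict:
    """Counts per exact complex size plus the 3 / 4 / 5+ binning."""
    raw = Counter(ps.sizes())
    bins = {
        "3": raw.get(3, 0),
        "4": raw.get(4, 0),
        "5+": sum(count for size, count in raw.items() if size >= 5),
    }
    return {"raw": dict(sorted(raw.items())), "bins": bins}


@dataclass
class EvaluationReport:
    """Match counts, the three headline metrics and the size histogram."""

    n_matched_pred: int
    n_matched_ref: int
    n_pred: int
    n_ref: int
    recall: float
    precision: float
    f1: float
    size_histogram: dict = field(default_factory=dict)
    threshold: float = DEFAULT_MATCH_THRESHOLD

    def as_dict(self) -> dict:
        return {
            "N_p": self.n_matched_pred,
            "N_r": self.n_matched_ref,
            "|PS|": self.n_pred,
            "|RS|": self.n_ref,
            "recall": self.recall,
            "precision": self.precision,
            "F1": self.f1,
            "threshold": self.threshold,
            "size_histogram": self.size_histogram,
        }


def evaluate(
    ps: ComplexSet, rs: ComplexSet, threshold: float = DEFAULT_MATCH_THRESHOLD
) -> EvaluationReport:
    """Score a prediction set against a reference set.

    Duplicate predicted complexes count once (the precision denominator must
    not be inflatable by duplicates); the reference set is used as
    distributed.  An empty prediction set yields zero precision and F1.
    """
    if len(rs) == 0:
        raise ValueError("reference complex set is empty")
    preds = ps.deduplicated().complexes
    refs = rs.complexes
    matched_pred = [False] * len(preds)
    matched_ref = [False] * len(refs)
    for i, p in enumerate(preds):
        for j, r in enumerate(refs):
            if affinity_score(p, r) >= threshold:
                matched_pred[i] = True
                matched_ref[j] = True
    n_p = sum(matched_pred)
    n_r = sum(matched_ref)
    recall = n_r / len(refs)
    if preds:
        precision = n_p / len(preds)
    else:
        precision = 0.0
        logger.info("empty prediction set: precision set to 0")
    f1 = 0.0 if recall + precision == 0 else 2 * recall * precision / (recall + precision)
    return EvaluationReport(
        n_matched_pred=n_p,
        n_matched_ref=n_r,
        n_pred=len(preds),
        n_ref=len(refs),
        recall=recall,
        precision=precision,
        f1=f1,
        size_histogram=size_distribution(ComplexSet(preds)),
        threshold=threshold,
    )


def overlap_ratio(ppi: nx.Graph, rs: ComplexSet) -> float:
    """Fraction of network proteins that appear in the reference catalogue."""
    nodes = set(ppi.nodes)
    if not nodes:
        raise ValueError("overlap ratio is undefined for an empty network")
    return len(nodes & rs.proteins()) / len(nodes)
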