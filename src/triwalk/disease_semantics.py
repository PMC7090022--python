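"""DAG-based disease semantic similarity with a kernel fallback.

Each disease annotated in the ontology induces a *closure*: the disease plus
all of its ancestors.  Two semantic similarity flavours are computed over
shared closure nodes:

* method 1 — each node contributes a value that decays by a factor
  ``delta`` per generation away from the disease (self-contribution 1,
  multi-parent nodes take the max over child contributions);
* method 2 — each node contributes an information-content value
  ``-log(fraction of disease closures containing it)``, so terms shared by
  every disease contribute nothing and rare terms contribute a lot.

Diseases without a DAG annotation cannot be scored semantically; for any
pair involving such a disease the fused similarity falls back to the
Gaussian interaction-profile kernel over miRNA association profiles.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .containers import DiseaseOntology, EntityUniverse, SimilarityMatrix

logger = logging.getLogger(__name__)

DEFAULT_DELTA = 0.5


@dataclass(frozen=True)
class DiseaseDagClosure:
    """A disease, its ancestor closure, and per-node decay contributions."""

    disease: str
    nodes: frozenset[str]
    contributions_m1: Mapping[str, float]
    delta: float

    @property
    def ds1(self) -> float:
        """Method-1 semantic value: the sum of all node contributions."""
        return float(sum(self.contributions_m1.values()))


@dataclass
class SemanticValueTable:
    """Per-disease semantic values and per-term method-2 contributions."""

    ds1: dict[str, float]
    ds2: dict[str, float]
    ic_m2: dict[str, float]


def build_closure(
    ontology: DiseaseOntology, disease: str, delta: float = DEFAULT_DELTA
) -> DiseaseDagClosure:
    """Ancestor closure with per-generation decay contributions.

    The disease contributes 1 to itself; an ancestor's contribution is
    ``delta`` times the largest contribution among its children inside the
    closure, so contributions decay along every child-to-ancestor chain.
    """
    if not 0.0 < delta < 1.0:
        raise ValueError("contribution factor delta must lie in (0, 1)")
    nodes = ontology.closure_nodes(disease)  # raises KeyError on unknown disease
    sub = ontology.graph.subgraph(nodes)
    contributions: dict[str, float] = {}
    # child->parent edges: topological order yields children before parents
    for node in nx.topological_sort(sub):
        if node == disease:
            contributions[node] = 1.0
        else:
            contributions[node] = delta * max(
                contributions[c] for c in sub.predecessors(node) if c in contributions
            )
    return DiseaseDagClosure(disease, nodes, contributions, delta)


def semantic_similarity_m1(ci: DiseaseDagClosure, cj: DiseaseDagClosure) -> float:
    """Shared-node contribution mass relative to the two semantic values."""
    if ci.delta != cj.delta:
        raise ValueError("closures were built with different contribution factors")
    shared = ci.nodes & cj.nodes
    num = sum(ci.contributions_m1[t] + cj.contributions_m1[t] for t in shared)
    return float(num / (ci.ds1 + cj.ds1))


def ic_contribution_m2(closures: Sequence[DiseaseDagClosure]) -> dict[str, float]:
    """Per-term information content: -log(closure frequency of the term)."""
    n = len(closures)
    if n == 0:
        raise ValueError("no disease closures given")
    counts: dict[str, int] = {}
    for c in closures:
        for t in c.nodes:
            counts[t] = counts.get(t, 0) + 1
    return {t: -math.log(k / n) for t, k in counts.items()}


def semantic_value_table(closures: Sequence[DiseaseDagClosure]) -> SemanticValueTable:
    ic = ic_contribution_m2(closures)
    ds1 = {c.disease: c.ds1 for c in closures}
    ds2 = {c.disease: float(sum(ic[t] for t in c.nodes)) for c in closures}
    return SemanticValueTable(ds1, ds2, ic)


def semantic_similarity_m2(
    ci: DiseaseDagClosure,
    cj: DiseaseDagClosure,
    table: SemanticValueTable,
    denominator: str = "ds2",
) -> float:
    """Information-content analogue of method 1 over shared closure nodes.

    ``denominator="ds2"`` (default) normalizes by the summed method-2
    contributions so self-similarity is 1; ``"ds1"`` normalizes by the
    method-1 semantic values instead.
    """
    if denominator not in ("ds2", "ds1"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    shared = ci.nodes & cj.nodes
    num = sum(2.0 * table.ic_m2.get(t, 0.0) for t in shared)
    if denominator == "ds2":
        den = table.ds2[ci.disease] + table.ds2[cj.disease]
    else:
        den = table.ds1[ci.disease] + table.ds1[cj.disease]
    if den == 0.0:
        logger.warning(
            "zero semantic-value denominator for (%s, %s); similarity set to 0",
            ci.disease,
            cj.disease,
        )
        return 0.0
    return float(num / den)


def semantic_similarity_matrices(
    ontology: DiseaseOntology,
    diseases: Iterable[str],
    delta: float = DEFAULT_DELTA,
    denominator: str = "ds2",
):
    """Method-1 and method-2 similarity matrices over annotated diseases.

    ``diseases`` is filtered to those present in the ontology; returns
    ``(annotated_ids, m1, m2)`` with matrices in the sorted order of the
    annotated ids.
    """
    annotated = sorted(d for d in diseases if d in ontology.terms)
    closures = [build_closure(ontology, d, delta) for d in annotated]
    table = semantic_value_table(closures) if closures else SemanticValueTable({}, {}, {})
    n = len(annotated)
    m1 = np.eye(n)
    m2 = np.eye(n)
    for i in range(n):
        m2[i, i] = semantic_similarity_m2(closures[i], closures[i], table, denominator)
        for j in range(i + 1, n):
            m1[i, j] = m1[j, i] = semantic_similarity_m1(closures[i], closures[j])
            m2[i, j] = m2[j, i] = semantic_similarity_m2(
                closures[i], closures[j], table, denominator
            )
    return annotated, m1, m2


def fused_disease_similarity(
    universe: EntityUniverse,
    annotated: Sequence[str],
    m1: np.ndarray,
    m2: np.ndarray,
    gip: SimilarityMatrix,
) -> SimilarityMatrix:
    """Average of the two semantic similarities where both diseases carry a
    DAG closure; Gaussian interaction-profile kernel otherwise."""
    if gip.universe.ids != universe.ids:
        raise ValueError("kernel similarity not aligned to the disease universe")
    n = len(universe)
    out = gip.values.copy()
    pos = {d: k for k, d in enumerate(annotated)}
    idx = [universe.index(d) for d in annotated]
    for a, d_i in enumerate(annotated):
        for b, d_j in enumerate(annotated):
            out[idx[a], idx[b]] = (m1[pos[d_i], pos[d_j]] + m2[pos[d_i], pos[d_j]]) / 2.0
    np.fill_diagonal(out, 1.0)
    return SimilarityMatrix(universe, out)
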