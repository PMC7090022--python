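"""Typed in-memory containers for the triple-layer heterogeneous network.

The network has three entity layers (small molecules, miRNAs, diseases)
connected by binary bipartite association matrices and intra-layer similarity
matrices.  Every matrix is indexed by an :class:`EntityUniverse`, whose id
order is always the lexicographic sort of the ids — this makes every
downstream matrix reproducible bit-for-bit from the same input files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

KINDS = ("small_molecule", "mirna", "disease")

_SYM_TOL = 1e-9


@dataclass(frozen=True)
class EntityUniverse:
    """An ordered set of entity identifiers of one kind.

    Ids are unique, non-empty and sorted lexicographically; the sort order
    defines row/column order of every matrix built over this universe.
    """

    kind: str
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown entity kind {self.kind!r}; expected one of {KINDS}")
        if len(self.ids) == 0:
            raise ValueError("empty entity universe")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate entity ids in universe")
        if list(self.ids) != sorted(self.ids):
            raise ValueError("universe ids must be lexicographically sorted")

    @classmethod
    def from_ids(cls, kind: str, ids: Iterable[str]) -> "EntityUniverse":
        """Build a universe from arbitrary ids (deduplicated and sorted)."""
        return cls(kind, tuple(sorted(set(map(str, ids)))))

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, item: object) -> bool:
        return item in self.indexer

    @property
    def indexer(self) -> Mapping[str, int]:
        try:
            return object.__getattribute__(self, "_indexer")
        except AttributeError:
            idx = {e: i for i, e in enumerate(self.ids)}
            object.__setattr__(self, "_indexer", idx)
            return idx

    def index(self, entity_id: str) -> int:
        try:
            return self.indexer[entity_id]
        except KeyError:
            raise KeyError(f"unknown {self.kind} id {entity_id!r}") from None

    def union(self, other: "EntityUniverse") -> "EntityUniverse":
        if other.kind != self.kind:
            raise ValueError(f"cannot union universes of kind {self.kind!r} and {other.kind!r}")
        return EntityUniverse.from_ids(self.kind, set(self.ids) | set(other.ids))


@dataclass
class AssociationTable:
    """Binary bipartite association matrix with named row/column entities."""

    rows: EntityUniverse
    cols: EntityUniverse
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError(
                f"association matrix shape {self.values.shape} does not match "
                f"universes ({len(self.rows)}, {len(self.cols)})"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("association matrix must be binary")
        self.values = self.values.astype(np.int8)

    @property
    def n_edges(self) -> int:
        return int(self.values.sum())

    def edges(self) -> list[tuple[str, str]]:
        """Present (row_id, col_id) pairs, in row-major (sorted) order."""
        ii, jj = np.nonzero(self.values)
        return [(self.rows.ids[i], self.cols.ids[j]) for i, j in zip(ii, jj)]

    def without_edges(self, pairs: Iterable[tuple[str, str]]) -> "AssociationTable":
        """A copy with the given edges removed (used to mask test folds)."""
        vals = self.values.copy()
        for r, c in pairs:
            vals[self.rows.index(r), self.cols.index(c)] = 0
        return AssociationTable(self.rows, self.cols, vals)

    def reindex(
        self, rows: EntityUniverse | None = None, cols: EntityUniverse | None = None
    ) -> "AssociationTable":
        rows = rows or self.rows
        cols = cols or self.cols
        out = np.zeros((len(rows), len(cols)), dtype=np.int8)
        ri = [rows.index(r) for r in self.rows.ids if r in rows]
        ci = [cols.index(c) for c in self.cols.ids if c in cols]
        keep_r = [i for i, r in enumerate(self.rows.ids) if r in rows]
        keep_c = [j for j, c in enumerate(self.cols.ids) if c in cols]
        out[np.ix_(ri, ci)] = self.values[np.ix_(keep_r, keep_c)]
        return AssociationTable(rows, cols, out)


@dataclass
class PriorMatrix:
    """Nonnegative prior over an association table's cells.

    Built from an association table with E edges, each present edge carries
    mass 1/E so the prior sums to one.
    """

    rows: EntityUniverse
    cols: EntityUniverse
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.rows), len(self.cols)):
            raise ValueError("prior matrix shape does not match universes")


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity in [0, 1] with unit diagonal."""

    universe: EntityUniverse
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.universe)
        if self.values.shape != (n, n):
            raise ValueError(f"similarity shape {self.values.shape} != ({n}, {n})")
        if not np.allclose(self.values, self.values.T, atol=_SYM_TOL):
            raise ValueError("similarity matrix is not symmetric")
        if self.values.min() < -_SYM_TOL or self.values.max() > 1 + _SYM_TOL:
            raise ValueError("similarity entries outside [0, 1]")
        if not np.allclose(np.diag(self.values), 1.0, atol=_SYM_TOL):
            raise ValueError("similarity diagonal must be 1")
        # normalize away float fuzz so invariants hold exactly downstream
        self.values = np.clip((self.values + self.values.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(self.values, 1.0)

    def reindex(self, universe: EntityUniverse) -> "SimilarityMatrix":
        """Embed into a larger universe: new entities get 0 off-diagonal, 1 diagonal."""
        n = len(universe)
        out = np.eye(n)
        pos = [universe.index(e) for e in self.universe.ids if e in universe]
        keep = [i for i, e in enumerate(self.universe.ids) if e in universe]
        out[np.ix_(pos, pos)] = self.values[np.ix_(keep, keep)]
        np.fill_diagonal(out, 1.0)
        return SimilarityMatrix(universe, out)


@dataclass
class AnnotationProfiles:
    """Per-entity sets of annotation terms (side effects, diseases, target genes)."""

    universe: EntityUniverse
    term_sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        unknown = set(self.term_sets) - set(self.universe.ids)
        if unknown:
            raise ValueError(f"profile entities not in universe: {sorted(unknown)[:5]}")
        self.term_sets = {e: frozenset(map(str, s)) for e, s in self.term_sets.items()}

    def terms(self, entity_id: str) -> frozenset[str]:
        return self.term_sets.get(entity_id, frozenset())

    def reindex(self, universe: EntityUniverse) -> "AnnotationProfiles":
        kept = {e: s for e, s in self.term_sets.items() if e in universe}
        return AnnotationProfiles(universe, kept)


@dataclass(frozen=True)
class DiseaseOntology:
    """A DAG of disease terms given as (child, parent) edges."""

    terms: frozenset[str]
    parent_edges: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        endpoints = {t for e in self.parent_edges for t in e}
        if not endpoints <= self.terms:
            raise ValueError("edge endpoint not in term set")
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise ValueError(f"ontology contains a cycle through {cycle[0][0]!r}")

    @property
    def graph(self) -> nx.DiGraph:
        """Child -> parent digraph over all terms."""
        g = nx.DiGraph()
        g.add_nodes_from(sorted(self.terms))
        g.add_edges_from(sorted(self.parent_edges))
        return g

    def closure_nodes(self, term: str) -> frozenset[str]:
        """The term plus all of its ancestors."""
        if term not in self.terms:
            raise KeyError(f"unknown ontology term {term!r}")
        return frozenset(nx.descendants(self.graph, term)) | {term}
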