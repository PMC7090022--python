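"""Readers, writers and universe alignment for network input files.

Formats are deliberately plain text:

* edge lists — 2-column whitespace/tab-delimited files, ``#`` comments;
* similarity matrices — dense TSV/CSV with a header row and an index column
  (the carrier for externally computed matrices, e.g. chemical-structure
  similarity from a graph-matching tool);
* annotation profiles — 2-column (entity, term) files;
* disease ontology — 2-column (child, parent) files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .containers import (
    AnnotationProfiles,
    AssociationTable,
    DiseaseOntology,
    EntityUniverse,
    PriorMatrix,
    SimilarityMatrix,
)

logger = logging.getLogger(__name__)


class ParseError(ValueError):
    """Raised when an input file is malformed."""


def _data_lines(path: str | Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    pairs = []
    for lineno, line in _data_lines(path):
        fields = line.split()
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        pairs.append((fields[0], fields[1]))
    return pairs


def read_edge_list(path: str | Path, row_kind: str, col_kind: str) -> AssociationTable:
    """Read a bipartite association edge list into a binary table.

    Universes are the sorted distinct ids of each column; duplicate lines
    collapse to a single edge.
    """
    pairs = _read_pairs(path)
    if not pairs:
        raise ParseError(f"{path}: no edges")
    rows = EntityUniverse.from_ids(row_kind, (r for r, _ in pairs))
    cols = EntityUniverse.from_ids(col_kind, (c for _, c in pairs))
    values = np.zeros((len(rows), len(cols)), dtype=np.int8)
    for r, c in pairs:
        values[rows.index(r), cols.index(c)] = 1
    return AssociationTable(rows, cols, values)


def write_edge_list(table: AssociationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# {table.rows.kind}\t{table.cols.kind}\n")
        for r, c in table.edges():
            fh.write(f"{r}\t{c}\n")


def normalize_prior(table: AssociationTable) -> PriorMatrix:
    """Spread unit mass uniformly over the present edges (1/E per edge)."""
    e = table.n_edges
    if e == 0:
        raise ValueError("empty association table")
    return PriorMatrix(table.rows, table.cols, table.values.astype(float) / e)


def read_similarity_matrix(path: str | Path, kind: str) -> SimilarityMatrix:
    """Read a dense square similarity matrix.

    The body is symmetrized as (M + M')/2 and clipped to [0, 1] (external
    tools emit asymmetric and occasionally out-of-range scores); the diagonal
    is forced to 1.  A warning is logged whenever a repair was needed.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] != df.shape[1]:
        raise ParseError(f"{path}: non-square matrix {df.shape}")
    if not all(df.index.astype(str) == df.columns.astype(str)):
        # align columns to the row order when both carry the same label set
        if set(df.index.astype(str)) != set(df.columns.astype(str)):
            raise ParseError(f"{path}: row and column labels differ")
        df = df[df.index]
    bad = df.apply(pd.to_numeric, errors="coerce")
    if bad.isna().any().any():
        i, j = np.argwhere(bad.isna().values)[0]
        raise ParseError(f"{path}: non-numeric cell at row {df.index[i]!r}, col {df.columns[j]!r}")
    df.index = df.index.astype(str)
    df = bad.sort_index(axis=0)[sorted(bad.columns.astype(str))]
    values = df.to_numpy(dtype=float)
    sym = (values + values.T) / 2.0
    if not np.allclose(sym, values, atol=1e-12):
        logger.warning("%s: asymmetric similarity matrix symmetrized as (M + M')/2", path)
    clipped = np.clip(sym, 0.0, 1.0)
    if not np.array_equal(clipped, sym):
        logger.warning("%s: similarity entries outside [0, 1] clipped", path)
    np.fill_diagonal(clipped, 1.0)
    universe = EntityUniverse.from_ids(kind, df.index)
    return SimilarityMatrix(universe, clipped)


def write_similarity_matrix(matrix: SimilarityMatrix, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    pd.DataFrame(
        matrix.values, index=matrix.universe.ids, columns=matrix.universe.ids
    ).to_csv(path, sep=sep)


def read_profiles(path: str | Path, kind: str) -> AnnotationProfiles:
    """Read (entity, term) pairs into annotation profiles."""
    pairs = _read_pairs(path)
    if not pairs:
        raise ParseError(f"{path}: no annotations")
    universe = EntityUniverse.from_ids(kind, (e for e, _ in pairs))
    sets: dict[str, set[str]] = {}
    for e, t in pairs:
        sets.setdefault(e, set()).add(t)
    return AnnotationProfiles(universe, {e: frozenset(s) for e, s in sets.items()})


def write_profiles(profiles: AnnotationProfiles, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# entity\tterm\n")
        for e in profiles.universe.ids:
            for t in sorted(profiles.terms(e)):
                fh.write(f"{e}\t{t}\n")


def read_disease_dag(path: str | Path) -> DiseaseOntology:
    """Read a (child, parent) edge file; acyclicity is verified on load."""
    pairs = _read_pairs(path)
    terms = {t for e in pairs for t in e}
    return DiseaseOntology(frozenset(terms), frozenset(pairs))


def write_disease_dag(ontology: DiseaseOntology, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# child\tparent\n")
        for c, p in sorted(ontology.parent_edges):
            fh.write(f"{c}\t{p}\n")


@dataclass
class AlignmentReport:
    """Which ids each object gained when re-indexed onto the union universe."""

    kind: str
    universe: EntityUniverse
    added: list[tuple[str, ...]] = field(default_factory=list)


def _universe_of(obj, kind: str) -> EntityUniverse:
    if isinstance(obj, SimilarityMatrix):
        u = obj.universe
    elif isinstance(obj, AnnotationProfiles):
        u = obj.universe
    elif isinstance(obj, AssociationTable):
        if obj.rows.kind == kind:
            u = obj.rows
        elif obj.cols.kind == kind:
            u = obj.cols
        else:
            raise ValueError(f"association table has no {kind!r} axis")
    else:
        raise TypeError(f"cannot align object of type {type(obj).__name__}")
    if u.kind != kind:
        raise ValueError(f"object universe kind {u.kind!r} != {kind!r}")
    return u


def align_universes(objects: Sequence, kind: str):
    """Re-index every object onto the union universe of the given kind.

    Missing similarity rows are padded with 0 off-diagonal / 1 diagonal;
    missing association rows/columns with 0; missing profiles stay empty.
    Returns ``(aligned_objects, report)``.
    """
    universes = [_universe_of(o, kind) for o in objects]
    if not universes:
        raise ValueError("nothing to align")
    union = universes[0]
    for u in universes[1:]:
        union = union.union(u)
    report = AlignmentReport(kind, union)
    aligned = []
    for obj, u in zip(objects, universes):
        report.added.append(tuple(e for e in union.ids if e not in u))
        if isinstance(obj, SimilarityMatrix) or isinstance(obj, AnnotationProfiles):
            aligned.append(obj.reindex(union))
        else:  # AssociationTable
            if obj.rows.kind == kind:
                aligned.append(obj.reindex(rows=union))
            else:
                aligned.append(obj.reindex(cols=union))
    return aligned, report
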