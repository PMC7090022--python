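"""Assemble fused similarity matrices from raw inputs.

Small-molecule similarity fuses four sources (side-effect Jaccard, an
externally computed chemical-structure matrix, disease-phenotype Jaccard
from small-molecule–disease associations, and target-gene Jaccard standing
in for gene-set functional similarity); miRNA similarity fuses two
(disease-phenotype Jaccard from miRNA–disease associations, target-gene
Jaccard).  Disease similarity averages the two DAG semantic methods where
both diseases are annotated and falls back to the Gaussian
interaction-profile kernel over miRNA association profiles otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

from .containers import (
    AnnotationProfiles,
    AssociationTable,
    DiseaseOntology,
    EntityUniverse,
    SimilarityMatrix,
)
from .disease_semantics import (
    DEFAULT_DELTA,
    fused_disease_similarity,
    semantic_similarity_matrices,
)
from .similarity import FusionWeights, fuse_similarities, gip_bandwidth, gip_kernel, jaccard_similarity
from .synthetic import Benchmark


@dataclass
class NetworkBundle:
    """Everything the walk and the evaluation harness need, aligned."""

    B: AssociationTable
    C: AssociationTable
    SD: AssociationTable
    Ss: SimilarityMatrix
    Sm: SimilarityMatrix
    Sd: SimilarityMatrix


def align_benchmark(benchmark: Benchmark) -> Benchmark:
    """Re-index all parts of a bundle onto shared per-kind union universes.

    Needed when parts were read from separate files: an entity with no edge
    in one file would otherwise be missing from that file's universe.
    """
    from dataclasses import replace

    from .io import align_universes

    sm_objs, _ = align_universes(
        [benchmark.B, benchmark.SD, benchmark.sm_side_effects,
         benchmark.sm_targets, benchmark.chem_similarity],
        "small_molecule",
    )
    B, SD, side_effects, targets, chem = sm_objs
    mir_objs, _ = align_universes([B, benchmark.C, benchmark.mirna_targets], "mirna")
    B, C, mirna_targets = mir_objs
    dis_objs, _ = align_universes([C, SD], "disease")
    C, SD = dis_objs
    return replace(
        benchmark,
        B=B, C=C, SD=SD,
        sm_side_effects=side_effects, sm_targets=targets,
        mirna_targets=mirna_targets, chem_similarity=chem,
    )


def profiles_from_associations(table: AssociationTable, axis: str = "rows") -> AnnotationProfiles:
    """Interpret one axis of an association table as annotation profiles
    (e.g. each small molecule's set of associated diseases)."""
    if axis == "rows":
        sets = {
            r: frozenset(c for c, v in zip(table.cols.ids, row) if v)
            for r, row in zip(table.rows.ids, table.values)
        }
        return AnnotationProfiles(table.rows, sets)
    if axis == "cols":
        sets = {
            c: frozenset(r for r, v in zip(table.rows.ids, col) if v)
            for c, col in zip(table.cols.ids, table.values.T)
        }
        return AnnotationProfiles(table.cols, sets)
    raise ValueError(f"axis must be 'rows' or 'cols', got {axis!r}")


def transpose_table(table: AssociationTable) -> AssociationTable:
    return AssociationTable(table.cols, table.rows, table.values.T)


def build_small_molecule_similarity(
    side_effects: AnnotationProfiles,
    chemical: SimilarityMatrix,
    SD: AssociationTable,
    targets: AnnotationProfiles,
    weights: FusionWeights | None = None,
) -> SimilarityMatrix:
    sources = [
        jaccard_similarity(side_effects),
        chemical,
        jaccard_similarity(profiles_from_associations(SD, "rows")),
        jaccard_similarity(targets),
    ]
    return fuse_similarities(sources, weights or FusionWeights.equal(4))


def build_mirna_similarity(
    C: AssociationTable,
    targets: AnnotationProfiles,
    weights: FusionWeights | None = None,
) -> SimilarityMatrix:
    sources = [
        jaccard_similarity(profiles_from_associations(C, "rows")),
        jaccard_similarity(targets),
    ]
    return fuse_similarities(sources, weights or FusionWeights.equal(2))


def build_disease_similarity(
    C: AssociationTable,
    ontology: DiseaseOntology,
    delta: float = DEFAULT_DELTA,
    gamma_prime: float = 1.0,
    bandwidth_mode: str = "divide",
    m2_denominator: str = "ds2",
) -> SimilarityMatrix:
    disease_universe: EntityUniverse = C.cols
    annotated, m1, m2 = semantic_similarity_matrices(
        ontology, disease_universe.ids, delta=delta, denominator=m2_denominator
    )
    profile_table = transpose_table(C)  # disease x miRNA interaction profiles
    bw = gip_bandwidth(profile_table, gamma_prime=gamma_prime, mode=bandwidth_mode)
    gip = gip_kernel(profile_table, bw)
    return fused_disease_similarity(disease_universe, annotated, m1, m2, gip)


def build_bundle(
    benchmark: Benchmark,
    sm_weights: FusionWeights | None = None,
    mirna_weights: FusionWeights | None = None,
    delta: float = DEFAULT_DELTA,
    gamma_prime: float = 1.0,
    bandwidth_mode: str = "divide",
    m2_denominator: str = "ds2",
) -> NetworkBundle:
    """Fuse all similarity sources of a benchmark into a walk-ready bundle."""
    Ss = build_small_molecule_similarity(
        benchmark.sm_side_effects,
        benchmark.chem_similarity,
        benchmark.SD,
        benchmark.sm_targets,
        sm_weights,
    )
    Sm = build_mirna_similarity(benchmark.C, benchmark.mirna_targets, mirna_weights)
    Sd = build_disease_similarity(
        benchmark.C,
        benchmark.ontology,
        delta=delta,
        gamma_prime=gamma_prime,
        bandwidth_mode=bandwidth_mode,
        m2_denominator=m2_denominator,
    )
    return NetworkBundle(benchmark.B, benchmark.C, benchmark.SD, Ss, Sm, Sd)
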