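"""Planted-structure synthetic benchmarks for the full pipeline.

The generator emulates the shape of the real inputs — bipartite association
tables, annotation profiles, a precomputed chemical similarity matrix, and a
disease ontology — with planted cluster structure: every small molecule,
miRNA and disease belongs to one of ``n_clusters`` groups, associations are
dense inside matched groups and sparse across them, annotation terms are
drawn from cluster-specific pools, and cluster-mate diseases share ontology
subtrees.  Guilt-by-association therefore holds by construction, which is
exactly the assumption the negative selection and the walk exploit — so
cross-validated ranking quality on these benchmarks is a meaningful
end-to-end check.  Everything is determined by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import json

import numpy as np

from .containers import (
    AnnotationProfiles,
    AssociationTable,
    DiseaseOntology,
    EntityUniverse,
    SimilarityMatrix,
)
from . import io as tio


@dataclass(frozen=True)
class SyntheticConfig:
    """Benchmark shape; defaults give ~660 positive associations."""

    n_sm: int = 100
    n_mirna: int = 80
    n_disease: int = 30
    n_clusters: int = 4
    p_in: float = 0.3
    p_out: float = 0.01
    sim_noise: float = 0.05
    n_terms_per_entity: int = 8
    dag_depth: int = 3
    unannotated_fraction: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_out < self.p_in <= 1.0:
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_clusters > min(self.n_sm, self.n_mirna, self.n_disease):
            raise ValueError("n_clusters exceeds the smallest entity count")
        if self.n_clusters < 1 or self.sim_noise < 0:
            raise ValueError("invalid cluster count or similarity noise")
        if self.dag_depth < 1 or self.n_terms_per_entity < 1:
            raise ValueError("dag_depth and n_terms_per_entity must be >= 1")
        if not 0.0 <= self.unannotated_fraction < 1.0:
            raise ValueError("unannotated_fraction must lie in [0, 1)")


@dataclass
class Benchmark:
    """A complete synthetic input bundle plus ground-truth cluster labels."""

    config: SyntheticConfig | None
    B: AssociationTable  # small molecule x miRNA
    C: AssociationTable  # miRNA x disease
    SD: AssociationTable  # small molecule x disease
    sm_side_effects: AnnotationProfiles
    sm_targets: AnnotationProfiles
    mirna_targets: AnnotationProfiles
    chem_similarity: SimilarityMatrix
    ontology: DiseaseOntology
    labels: dict[str, np.ndarray] = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tio.write_edge_list(self.B, outdir / "sm_mirna.tsv")
        tio.write_edge_list(self.C, outdir / "mirna_disease.tsv")
        tio.write_edge_list(self.SD, outdir / "sm_disease.tsv")
        tio.write_profiles(self.sm_side_effects, outdir / "sm_side_effects.tsv")
        tio.write_profiles(self.sm_targets, outdir / "sm_targets.tsv")
        tio.write_profiles(self.mirna_targets, outdir / "mirna_targets.tsv")
        tio.write_similarity_matrix(self.chem_similarity, outdir / "sm_chemical_similarity.tsv")
        tio.write_disease_dag(self.ontology, outdir / "disease_dag.tsv")
        manifest = {"n_positive_associations": self.B.n_edges}
        if self.config is not None:
            manifest["config"] = {
                k: getattr(self.config, k) for k in self.config.__dataclass_fields__
            }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _bipartite(rows, cols, row_lab, col_lab, p_in, p_out, rng) -> AssociationTable:
    match = row_lab[:, None] == col_lab[None, :]
    probs = np.where(match, p_in, p_out)
    values = (rng.random(probs.shape) < probs).astype(np.int8)
    return AssociationTable(rows, cols, values)


def _profiles(universe, labels, prefix, n_terms, rng) -> AnnotationProfiles:
    """Cluster-pool term draws plus a little shared noise."""
    pools = {
        g: [f"{prefix}_c{g:02d}_{t:02d}" for t in range(2 * n_terms)]
        for g in np.unique(labels)
    }
    shared = [f"{prefix}_shared_{t:02d}" for t in range(4 * n_terms)]
    sets = {}
    for e, g in zip(universe.ids, labels):
        own = rng.choice(pools[g], size=n_terms, replace=False)
        noise = rng.choice(shared, size=2, replace=False)
        sets[e] = frozenset(own) | frozenset(noise)
    return AnnotationProfiles(universe, sets)


def _cluster_similarity(universe, labels, sim_noise, rng) -> SimilarityMatrix:
    base = np.where(labels[:, None] == labels[None, :], 0.8, 0.1)
    noise = rng.normal(0.0, sim_noise, size=base.shape)
    noisy = base + (noise + noise.T) / 2.0
    np.fill_diagonal(noisy, 1.0)
    return SimilarityMatrix(universe, np.clip(noisy, 0.0, 1.0))


def _ontology(universe, labels, depth, unannotated_fraction, rng) -> DiseaseOntology:
    """Per-cluster subtrees of the given depth; a fraction of diseases is
    left out of the DAG to exercise the kernel fallback."""
    edges: set[tuple[str, str]] = set()
    terms: set[str] = set()
    levels_by_cluster: dict[int, list[str]] = {}
    for g in np.unique(labels):
        root = f"anc_c{g:02d}_L0_0"
        terms.add(root)
        prev = [root]
        for lvl in range(1, depth):
            cur = [f"anc_c{g:02d}_L{lvl}_{k}" for k in range(2)]
            for node in cur:
                parent = prev[rng.integers(len(prev))]
                edges.add((node, parent))
                terms.add(node)
            prev = cur
        levels_by_cluster[int(g)] = prev
    n = len(universe)
    n_unannotated = int(round(unannotated_fraction * n))
    unannotated = set(rng.choice(n, size=n_unannotated, replace=False).tolist())
    for i, (d, g) in enumerate(zip(universe.ids, labels)):
        if i in unannotated:
            continue
        deepest = levels_by_cluster[int(g)]
        parent = deepest[rng.integers(len(deepest))]
        edges.add((d, parent))
        terms.add(d)
    return DiseaseOntology(frozenset(terms), frozenset(edges))


def generate_benchmark(config: SyntheticConfig | None = None) -> Benchmark:
    """Generate the full input bundle from a single seed."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    sm_u = EntityUniverse("small_molecule", tuple(f"sm{i:04d}" for i in range(config.n_sm)))
    mir_u = EntityUniverse("mirna", tuple(f"mir{i:04d}" for i in range(config.n_mirna)))
    dis_u = EntityUniverse("disease", tuple(f"dis{i:04d}" for i in range(config.n_disease)))
    lab_sm = rng.integers(config.n_clusters, size=config.n_sm)
    lab_mir = rng.integers(config.n_clusters, size=config.n_mirna)
    lab_dis = rng.integers(config.n_clusters, size=config.n_disease)
    B = _bipartite(sm_u, mir_u, lab_sm, lab_mir, config.p_in, config.p_out, rng)
    C = _bipartite(mir_u, dis_u, lab_mir, lab_dis, config.p_in, config.p_out, rng)
    SD = _bipartite(sm_u, dis_u, lab_sm, lab_dis, config.p_in, config.p_out, rng)
    side_effects = _profiles(sm_u, lab_sm, "se", config.n_terms_per_entity, rng)
    sm_targets = _profiles(sm_u, lab_sm, "tgt", config.n_terms_per_entity, rng)
    mirna_targets = _profiles(mir_u, lab_mir, "mtg", config.n_terms_per_entity, rng)
    chem = _cluster_similarity(sm_u, lab_sm, config.sim_noise, rng)
    ontology = _ontology(dis_u, lab_dis, config.dag_depth, config.unannotated_fraction, rng)
    return Benchmark(
        config=config,
        B=B,
        C=C,
        SD=SD,
        sm_side_effects=side_effects,
        sm_targets=sm_targets,
        mirna_targets=mirna_targets,
        chem_similarity=chem,
        ontology=ontology,
        labels={"small_molecule": lab_sm, "mirna": lab_mir, "disease": lab_dis},
    )
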