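"""Profile-based similarities and multi-source fusion.

Three primitives cover every intra-layer similarity source the pipeline uses:

* Jaccard similarity over annotation term sets (side effects, associated
  diseases, target genes);
* the Gaussian interaction-profile (GIP) kernel over binary association
  profiles, with bandwidth standardized by the mean squared profile norm;
* entrywise weighted averaging of aligned similarity matrices.

Small-molecule similarity is fused from four sources (side effects, chemical
structure, disease phenotypes, target-gene function) and miRNA similarity
from two (disease phenotypes, target-gene function); defaults weight all
sources equally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .containers import AnnotationProfiles, AssociationTable, SimilarityMatrix


@dataclass(frozen=True)
class FusionWeights:
    """Nonnegative per-source weights for similarity fusion."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weights):
            raise ValueError("fusion weights must be nonnegative")
        if not any(w > 0 for w in self.weights):
            raise ValueError("at least one fusion weight must be positive")

    @classmethod
    def equal(cls, n: int) -> "FusionWeights":
        return cls((1.0,) * n)


@dataclass(frozen=True)
class KernelBandwidth:
    """Raw (gamma_prime) and standardized (gamma) GIP kernel bandwidth."""

    gamma_prime: float
    gamma: float

    def __post_init__(self) -> None:
        if self.gamma_prime <= 0 or self.gamma <= 0:
            raise ValueError("kernel bandwidth must be positive")


def jaccard_similarity(profiles: AnnotationProfiles) -> SimilarityMatrix:
    """Pairwise |A ∩ B| / |A ∪ B| over annotation term sets.

    Pairs with an empty union (either set empty) score 0; the diagonal is 1
    even for entities with no annotations, so the result is a valid
    similarity matrix.
    """
    ids = profiles.universe.ids
    all_terms = sorted({t for e in ids for t in profiles.terms(e)})
    n = len(ids)
    if not all_terms:
        return SimilarityMatrix(profiles.universe, np.eye(n))
    tindex = {t: k for k, t in enumerate(all_terms)}
    x = np.zeros((n, len(all_terms)))
    for i, e in enumerate(ids):
        for t in profiles.terms(e):
            x[i, tindex[t]] = 1.0
    inter = x @ x.T
    sizes = x.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(profiles.universe, sim)


def gip_bandwidth(
    table: AssociationTable, gamma_prime: float = 1.0, mode: str = "divide"
) -> KernelBandwidth:
    """Standardize the GIP bandwidth by the mean squared profile norm.

    Profiles are the *rows* of the association table.  In ``divide`` mode
    (the default, and the standard construction) ``gamma = gamma_prime / mu``
    where ``mu`` is the mean squared row norm, so denser association profiles
    get a flatter kernel; ``multiply`` instead scales ``gamma_prime`` *by*
    ``mu``.
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    if mode not in ("divide", "multiply"):
        raise ValueError(f"unknown bandwidth mode {mode!r}")
    sq_norms = (table.values.astype(float) ** 2).sum(axis=1)
    mu = float(sq_norms.mean())
    if mu == 0.0:
        raise ValueError("degenerate bandwidth: all interaction profiles are zero")
    gamma = gamma_prime / mu if mode == "divide" else gamma_prime * mu
    return KernelBandwidth(gamma_prime, gamma)


def gip_kernel(table: AssociationTable, bandwidth: KernelBandwidth) -> SimilarityMatrix:
    """Gaussian kernel exp(-gamma * ||ID(i) - ID(j)||^2) over row profiles."""
    x = table.values.astype(float)
    if len(table.rows) > 1:
        sq = squareform(pdist(x, metric="sqeuclidean"))
    else:
        sq = np.zeros((1, 1))
    sim = np.exp(-bandwidth.gamma * sq)
    np.fill_diagonal(sim, 1.0)
    return SimilarityMatrix(table.rows, sim)


def fuse_similarities(
    sources: Sequence[SimilarityMatrix], weights: FusionWeights | Sequence[float] | None = None
) -> SimilarityMatrix:
    """Entrywise weighted mean of aligned similarity matrices."""
    if len(sources) == 0:
        raise ValueError("no similarity sources to fuse")
    if weights is None:
        weights = FusionWeights.equal(len(sources))
    elif not isinstance(weights, FusionWeights):
        weights = FusionWeights(tuple(float(w) for w in weights))
    if len(weights.weights) != len(sources):
        raise ValueError(
            f"{len(weights.weights)} weights for {len(sources)} similarity sources"
        )
    universe = sources[0].universe
    for s in sources[1:]:
        if s.universe.ids != universe.ids or s.universe.kind != universe.kind:
            raise ValueError("similarity sources are not aligned to one universe")
    total = sum(weights.weights)
    fused = sum(w * s.values for w, s in zip(weights.weights, sources)) / total
    return SimilarityMatrix(universe, fused)
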