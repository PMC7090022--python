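"""Iterative random-walk propagation on the triple-layer network.

The state is a pair of score matrices: SM (small molecule × miRNA) and MD
(miRNA × disease).  Both start from uniform priors over the known edges
(each of E edges carries mass 1/E) and are updated for exactly
``max(l1, r1, l2, r2)`` steps:

* while ``t <= l1`` the SM update averages a restart-style walk in the
  small-molecule similarity network, ``alpha * Ss @ SM + (1 - alpha) * B``,
  with the disease bridge ``SD @ MD'`` that transfers miRNA–disease scores
  to small molecules sharing a disease; afterwards it walks in the miRNA
  similarity network, ``alpha * SM @ Sm + (1 - alpha) * B``;
* MD is updated symmetrically (gated by ``l2``, bridge ``SM' @ SD``, late
  walk in the disease similarity network), always using the *previous*
  iteration's SM.

``alpha`` penalizes long walks and anchors the state to the known
associations; there is no convergence loop — the step counts are the model.
Selected credible negatives can be stamped into the initial SM state with a
non-positive weight (default 0: they are bookkept for evaluation only).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import AssociationTable, PriorMatrix, SimilarityMatrix
from .io import normalize_prior
from .negatives import NegativeSampleSet

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class WalkConfig:
    """Walk parameters; defaults are the tuned operating point."""

    alpha: float = 0.4
    l1: int = 4
    r1: int = 1
    l2: int = 1
    r2: int = 1
    negative_prior_weight: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        for name in ("l1", "r1", "l2", "r2"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 10):
                raise ValueError(f"{name} must be an integer in 1..10")
        if self.negative_prior_weight > 0:
            raise ValueError("negative_prior_weight must be <= 0")
        if self.r1 > self.l1 or self.r2 > self.l2:
            logger.warning(
                "r1/r2 exceed l1/l2: the extra steps only extend the iteration count"
            )

    @property
    def n_iterations(self) -> int:
        return max(self.l1, self.r1, self.l2, self.r2)


@dataclass
class PredictionScores:
    """Final SM and MD score matrices plus per-iteration Frobenius deltas."""

    SM: np.ndarray
    MD: np.ndarray
    trace: list[tuple[float, float]] = field(default_factory=list)


def init_priors(
    B: AssociationTable,
    C: AssociationTable,
    negatives: NegativeSampleSet | None = None,
    config: WalkConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial SM/MD states: edge-uniform priors, negatives stamped into SM."""
    config = config or WalkConfig()
    sm0 = normalize_prior(B).values.copy()
    md0 = normalize_prior(C).values.copy()
    if negatives is not None:
        for sm, mirna in negatives.selected_pairs():
            sm0[B.rows.index(sm), B.cols.index(mirna)] = config.negative_prior_weight
    return sm0, md0


def walk_iterate(
    SM0: np.ndarray,
    MD0: np.ndarray,
    Ss: np.ndarray,
    Sm: np.ndarray,
    Sd: np.ndarray,
    SD: np.ndarray,
    B_prior: np.ndarray,
    C_prior: np.ndarray,
    config: WalkConfig,
) -> PredictionScores:
    """Run the fixed-step triple-layer propagation on raw arrays."""
    a = config.alpha
    sm = np.asarray(SM0, dtype=float)
    md = np.asarray(MD0, dtype=float)
    sd = np.asarray(SD, dtype=float)
    bp = np.asarray(B_prior, dtype=float)
    cp = np.asarray(C_prior, dtype=float)
    trace: list[tuple[float, float]] = []
    for t in range(1, config.n_iterations + 1):
        sm_prev = sm
        if t <= config.l1:
            sm1 = a * (Ss @ sm_prev) + (1.0 - a) * bp
            sm2 = sd @ md.T  # md is still MD^{t-1} here
            sm = (sm1 + sm2) / 2.0
        else:
            sm = a * (sm_prev @ Sm) + (1.0 - a) * bp
        if t <= config.l2:
            md1 = a * (Sm @ md) + (1.0 - a) * cp
            md2 = sm_prev.T @ sd
            md = (md1 + md2) / 2.0
        else:
            md = a * (md @ Sd) + (1.0 - a) * cp
        if not (np.isfinite(sm).all() and np.isfinite(md).all()):
            raise FloatingPointError(f"non-finite walk state at iteration {t}")
        trace.append(
            (float(np.linalg.norm(sm - sm_prev)), float(np.linalg.norm(md)))
        )
    return PredictionScores(sm, md, trace)


def run_walk(
    B: AssociationTable,
    C: AssociationTable,
    SD: AssociationTable,
    Ss: SimilarityMatrix,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    config: WalkConfig | None = None,
    negatives: NegativeSampleSet | None = None,
    B_prior: PriorMatrix | None = None,
    C_prior: PriorMatrix | None = None,
) -> PredictionScores:
    """Container-level wrapper: build priors and run the propagation."""
    config = config or WalkConfig()
    if Ss.universe.ids != B.rows.ids or Sm.universe.ids != B.cols.ids:
        raise ValueError("similarity matrices not aligned to the association table")
    if Sd.universe.ids != C.cols.ids or SD.cols.ids != C.cols.ids:
        raise ValueError("disease universes not aligned")
    if SD.rows.ids != B.rows.ids or C.rows.ids != B.cols.ids:
        raise ValueError("association tables not aligned")
    sm0, md0 = init_priors(B, C, negatives, config)
    bp = (B_prior or normalize_prior(B)).values
    cp = (C_prior or normalize_prior(C)).values
    return walk_iterate(
        sm0, md0, Ss.values, Sm.values, Sd.values, SD.values, bp, cp, config
    )


def predict(
    B: AssociationTable,
    C: AssociationTable,
    SD: AssociationTable,
    Ss: SimilarityMatrix,
    Sm: SimilarityMatrix,
    Sd: SimilarityMatrix,
    config: WalkConfig | None = None,
    negatives: NegativeSampleSet | None = None,
    top: int | None = None,
) -> pd.DataFrame:
    """Ranked small-molecule–miRNA score table.

    Returns a data frame (sm, mirna, score, known) sorted by score
    descending with deterministic id tie-breaks; ``known`` flags pairs
    already present in the association table.  ``top`` truncates the table.
    """
    scores = run_walk(B, C, SD, Ss, Sm, Sd, config=config, negatives=negatives)
    jj, kk = np.meshgrid(np.arange(len(B.rows)), np.arange(len(B.cols)), indexing="ij")
    df = pd.DataFrame(
        {
            "sm": [B.rows.ids[j] for j in jj.ravel()],
            "mirna": [B.cols.ids[k] for k in kk.ravel()],
            "score": scores.SM.ravel(),
            "known": B.values.ravel().astype(int),
        }
    )
    df = df.sort_values(
        ["score", "sm", "mirna"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return df.head(top) if top is not None else df
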