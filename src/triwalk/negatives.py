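"""Credible negative sample selection for small-molecule–miRNA pairs.

No repository of verified *non*-associations exists, so negatives must be
mined from the unobserved pairs.  The selection inverts guilt-by-association:
a small molecule dissimilar to every small molecule known to target an miRNA
— and an miRNA dissimilar to every miRNA known to be targeted by a small
molecule — is unlikely to form an association.  Each unobserved pair (j, k)
accumulates two similarity masses,

    ssm(j, k) = sum over small molecules l with B(l, k) = 1 of Ss(j, l)
    smr(j, k) = sum over miRNAs i with B(j, i) = 1 of Sm(i, k)

and is scored by the distance d = exp(-(ssm + smr)) in (0, 1]; the pairs
with the largest distance (least support from the positive set) are taken as
credible negatives.
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .containers import AssociationTable, SimilarityMatrix


@dataclass(frozen=True)
class NegativeSample:
    sm: str
    mirna: str
    ssm: float
    smr: float
    distance: float


@dataclass
class NegativeSampleSet:
    """All candidate negatives ranked by distance, with the top block selected."""

    samples: pd.DataFrame  # columns: sm, mirna, ssm, smr, distance, selected
    proportion: float
    n_selected: int

    @property
    def selected(self) -> pd.DataFrame:
        return self.samples[self.samples["selected"] == 1]

    def selected_pairs(self) -> set[tuple[str, str]]:
        return set(zip(self.selected["sm"], self.selected["mirna"]))


def credible_negative_scores(
    Ss: SimilarityMatrix, Sm: SimilarityMatrix, B: AssociationTable
) -> pd.DataFrame:
    """Distance scores for every unobserved pair of the association table.

    Returns a data frame with one row per zero cell of ``B`` (columns sm,
    mirna, ssm, smr, distance), unsorted.
    """
    if Ss.universe.ids != B.rows.ids:
        raise ValueError("small-molecule similarity not aligned to association rows")
    if Sm.universe.ids != B.cols.ids:
        raise ValueError("miRNA similarity not aligned to association columns")
    b = B.values.astype(float)
    ssm = Ss.values @ b  # (j,k): mass from small molecules targeting miRNA k
    smr = b @ Sm.values  # (j,k): mass from miRNAs targeted by small molecule j
    dist = np.exp(-(ssm + smr))
    jj, kk = np.nonzero(B.values == 0)
    return pd.DataFrame(
        {
            "sm": [B.rows.ids[j] for j in jj],
            "mirna": [B.cols.ids[k] for k in kk],
            "ssm": ssm[jj, kk],
            "smr": smr[jj, kk],
            "distance": dist[jj, kk],
        }
    )


def _selection_count(proportion: float, n_positives: int) -> int:
    # round half away from zero, at least one sample
    return max(1, int(math.floor(proportion * n_positives + 0.5)))


def select_negatives(
    candidates: pd.DataFrame, proportion: float, n_positives: int
) -> NegativeSampleSet:
    """Select the highest-distance candidates as credible negatives.

    ``proportion`` is relative to the positive count: 1.0 selects as many
    negatives as there are positives (capped at the candidate count).  Ties
    break deterministically by distance descending, then sm id, then miRNA id.
    """
    if len(candidates) == 0:
        raise ValueError("no candidate negative pairs")
    if not 0.0 < proportion <= 1.0:
        raise ValueError("proportion must lie in (0, 1]")
    n = min(_selection_count(proportion, n_positives), len(candidates))
    ranked = candidates.sort_values(
        ["distance", "sm", "mirna"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    ranked["selected"] = (ranked.index < n).astype(int)
    return NegativeSampleSet(ranked, proportion, n)
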