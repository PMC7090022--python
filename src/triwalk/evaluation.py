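"""Cross-validated evaluation of the association predictor.

Known positives are split into folds (leave-one-out or k-fold); for each
fold the test positives are masked out of the association table, the walk is
re-run on the training network, and the held-out positives are ranked
against the selected credible negatives.  AUC is rank-based; recall,
precision and accuracy come from a confusion matrix built by a documented
threshold rule (default: the top-P scores are predicted positive, with P
the number of test positives).  An ablation harness reruns the whole
cross-validation with uniformly random negatives in place of the credible
ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .containers import AssociationTable, SimilarityMatrix
from .negatives import NegativeSampleSet, credible_negative_scores, select_negatives
from .pipeline import NetworkBundle
from .walker import WalkConfig, run_walk

Pair = tuple[str, str]


@dataclass(frozen=True)
class FoldSpec:
    """Cross-validation layout: 'loocv' or 'kfold' (k ignored for loocv)."""

    mode: str = "kfold"
    k: int = 5
    seed: int = 0
    proportion: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("loocv", "kfold"):
            raise ValueError(f"unknown CV mode {self.mode!r}")
        if self.mode == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError("negative-sample proportion must lie in (0, 1]")


@dataclass
class MetricsReport:
    auc: float
    recall: float
    precision: float
    accuracy: float
    confusion: tuple[int, int, int, int]  # TP, FP, FN, TN
    threshold_rule: str = "rank:top-P"
    fold_aucs: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        tp, fp, fn, tn = self.confusion
        return {
            "auc": self.auc,
            "recall": self.recall,
            "precision": self.precision,
            "accuracy": self.accuracy,
            "confusion": {"TP": tp, "FP": fp, "FN": fn, "TN": tn},
            "threshold_rule": self.threshold_rule,
            "fold_aucs": self.fold_aucs,
        }


def make_folds(B: AssociationTable, spec: FoldSpec) -> list[tuple[list[Pair], list[Pair]]]:
    """Split the known positives into (train, test) folds."""
    positives = B.edges()
    n = len(positives)
    if n < 2:
        raise ValueError("need at least 2 positive associations for cross-validation")
    if spec.mode == "loocv":
        test_sets = [[p] for p in positives]
    else:
        if spec.k > n:
            raise ValueError(f"k={spec.k} exceeds the number of positives ({n})")
        rng = np.random.default_rng(spec.seed)
        order = rng.permutation(n)
        chunks = np.array_split(order, spec.k)
        test_sets = [[positives[i] for i in chunk] for chunk in chunks]
    folds = []
    for test in test_sets:
        test_set = set(test)
        folds.append(([p for p in positives if p not in test_set], list(test)))
    return folds


def score_fold(
    bundle: NetworkBundle,
    test_positives: Sequence[Pair],
    negatives: NegativeSampleSet,
    config: WalkConfig | None = None,
) -> pd.DataFrame:
    """Walk on the train-only network; return labeled scores.

    Test positives are masked out of the association table before the walk;
    the returned frame holds their scores (label 1) and the selected
    negatives' scores (label 0).
    """
    neg_pairs = sorted(negatives.selected_pairs())
    if not neg_pairs:
        raise ValueError("no negatives for evaluation")
    all_pos = set(bundle.B.edges())
    overlap = set(neg_pairs) & all_pos
    if overlap:
        raise ValueError(f"negatives overlap positives, e.g. {sorted(overlap)[0]}")
    B_train = bundle.B.without_edges(test_positives)
    scores = run_walk(
        B_train, bundle.C, bundle.SD, bundle.Ss, bundle.Sm, bundle.Sd,
        config=config, negatives=negatives,
    )
    rows, cols = bundle.B.rows, bundle.B.cols
    records = [
        (sm, mi, float(scores.SM[rows.index(sm), cols.index(mi)]), 1)
        for sm, mi in test_positives
    ] + [
        (sm, mi, float(scores.SM[rows.index(sm), cols.index(mi)]), 0)
        for sm, mi in neg_pairs
    ]
    return pd.DataFrame(records, columns=["sm", "mirna", "score", "label"])


def compute_metrics(scored: pd.DataFrame, threshold: float | None = None) -> MetricsReport:
    """Rank-based AUC plus threshold-rule confusion metrics.

    With ``threshold=None`` the top-P scored pairs are predicted positive,
    where P is the number of true positives in the frame; otherwise pairs
    with score >= threshold are predicted positive.
    """
    labels = scored["label"].to_numpy()
    scores = scored["score"].to_numpy()
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both positive and negative labels")
    auc = float(roc_auc_score(labels, scores))
    if threshold is None:
        order = np.argsort(-scores, kind="stable")
        predicted = np.zeros(len(labels), dtype=bool)
        predicted[order[:n_pos]] = True
        rule = "rank:top-P"
    else:
        predicted = scores >= threshold
        rule = f"score>={threshold}"
    tp = int((predicted & (labels == 1)).sum())
    fp = int((predicted & (labels == 0)).sum())
    fn = int((~predicted & (labels == 1)).sum())
    tn = int((~predicted & (labels == 0)).sum())
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    return MetricsReport(auc, recall, precision, accuracy, (tp, fp, fn, tn), rule)


def _aggregate(fold_reports: list[MetricsReport]) -> MetricsReport:
    conf = np.array([r.confusion for r in fold_reports]).sum(axis=0)
    tp, fp, fn, tn = (int(x) for x in conf)
    recall = tp / (tp + fn) if tp + fn else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    accuracy = (tp + tn) / conf.sum() if conf.sum() else 0.0
    aucs = [r.auc for r in fold_reports]
    return MetricsReport(
        float(np.mean(aucs)), recall, precision, accuracy, (tp, fp, fn, tn),
        fold_reports[0].threshold_rule, aucs,
    )


def cross_validate(
    bundle: NetworkBundle,
    spec: FoldSpec,
    config: WalkConfig | None = None,
    negatives: NegativeSampleSet | None = None,
    threshold: float | None = None,
) -> MetricsReport:
    """Full CV run; negatives default to credible negatives selected once
    from the complete positive set at the spec's proportion."""
    if negatives is None:
        candidates = credible_negative_scores(bundle.Ss, bundle.Sm, bundle.B)
        negatives = select_negatives(candidates, spec.proportion, bundle.B.n_edges)
    folds = make_folds(bundle.B, spec)
    reports = [
        compute_metrics(score_fold(bundle, test, negatives, config), threshold)
        for _, test in folds
    ]
    return _aggregate(reports)


def random_negatives(B: AssociationTable, n: int, seed: int) -> NegativeSampleSet:
    """Uniformly random unobserved pairs (the ablation baseline)."""
    jj, kk = np.nonzero(B.values == 0)
    if len(jj) == 0:
        raise ValueError("no unobserved pairs to sample from")
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(jj), size=min(n, len(jj)), replace=False)
    df = pd.DataFrame(
        {
            "sm": [B.rows.ids[j] for j in jj[pick]],
            "mirna": [B.cols.ids[k] for k in kk[pick]],
            "ssm": np.nan,
            "smr": np.nan,
            "distance": np.nan,
            "selected": 1,
        }
    )
    return NegativeSampleSet(df, proportion=n / max(B.n_edges, 1), n_selected=len(df))


@dataclass
class AblationReport:
    """Credible-negative arm vs random-negative arm, repeated over seeds."""

    credible_aucs: list[float]
    random_aucs: list[float]

    @property
    def mean_credible(self) -> float:
        return float(np.mean(self.credible_aucs))

    @property
    def mean_random(self) -> float:
        return float(np.mean(self.random_aucs))

    @property
    def delta(self) -> float:
        return self.mean_credible - self.mean_random

    def to_dict(self) -> dict:
        return {
            "credible_aucs": self.credible_aucs,
            "random_aucs": self.random_aucs,
            "mean_credible": self.mean_credible,
            "mean_random": self.mean_random,
            "delta": self.delta,
        }


def run_ablation(
    bundle: NetworkBundle,
    spec: FoldSpec,
    config: WalkConfig | None = None,
    n_repeats: int = 3,
) -> AblationReport:
    """Two CV arms differing only in how negatives are chosen."""
    candidates = credible_negative_scores(bundle.Ss, bundle.Sm, bundle.B)
    cns = select_negatives(candidates, spec.proportion, bundle.B.n_edges)
    cns_aucs, rnd_aucs = [], []
    for rep in range(n_repeats):
        rep_spec = replace(spec, seed=spec.seed + rep)
        rnd = random_negatives(bundle.B, cns.n_selected, seed=rep_spec.seed + 10_000)
        cns_aucs.append(cross_validate(bundle, rep_spec, config, negatives=cns).auc)
        rnd_aucs.append(cross_validate(bundle, rep_spec, config, negatives=rnd).auc)
    return AblationReport(cns_aucs, rnd_aucs)
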