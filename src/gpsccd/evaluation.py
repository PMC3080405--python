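"""Performance evaluation: Ac/Sn/Sp/MCC, ROC curves, self-consistency and k-fold CV.

Self-consistency scores every benchmark peptide against the full positive
reference set (training items meet themselves, so it upper-bounds the other
validations). Leave-one-out removes each positive from its own reference
set. k-fold cross-validation partitions the positive sites into k random
folds: held-out positives are scored against the retained folds' positives;
negatives — which never enter the reference set — are scored against each
fold's retained reference and averaged, keeping one pooled score per
negative. With k equal to the number of positives this reduces exactly
(bitwise, thanks to integer accumulation) to leave-one-out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .dataset import CleavageSite, Substrate, TrainingSet, build_training_set
from .matrix import SubstitutionMatrix
from .scoring import pairwise_raw_sums
from .training import (
    DEFAULT_SP_TARGET,
    loo_scores,
    self_consistency_scores,
    sn_at_sp,
)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary-classification tallies at one cutoff."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("confusion counts are all zero")


class Metrics(NamedTuple):
    ac: float
    sn: float
    sp: float
    mcc: float


def confusion_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, sensitivity, specificity and Matthews correlation.

    Ac=(TP+TN)/all, Sn=TP/(TP+FN), Sp=TN/(TN+FP),
    MCC=(TP*TN-FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    A metric whose denominator is zero is undefined and reported as NaN.
    """
    total = c.tp + c.fp + c.tn + c.fn
    ac = (c.tp + c.tn) / total
    sn = c.tp / (c.tp + c.fn) if c.tp + c.fn else math.nan
    sp = c.tn / (c.tn + c.fp) if c.tn + c.fp else math.nan
    denom = (
        (c.tp + c.fp) * (c.tp + c.fn) * (c.tn + c.fp) * (c.tn + c.fn)
    )
    mcc = (
        (c.tp * c.tn - c.fp * c.fn) / math.sqrt(denom) if denom else math.nan
    )
    return Metrics(ac=ac, sn=sn, sp=sp, mcc=mcc)


def counts_at_cutoff(
    positive_scores: np.ndarray, negative_scores: np.ndarray, cutoff: float
) -> ConfusionCounts:
    """Tally calls at ``score >= cutoff``."""
    pos = np.asarray(positive_scores)
    neg = np.asarray(negative_scores)
    tp = int(np.count_nonzero(pos >= cutoff))
    fp = int(np.count_nonzero(neg >= cutoff))
    return ConfusionCounts(tp=tp, fp=fp, tn=neg.size - fp, fn=pos.size - tp)


@dataclass(frozen=True)
class RocCurve:
    """ROC points (1-Sp, Sn) over all distinct cutoffs, with trapezoidal area."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    aroc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.thresholds, "sn": self.tpr, "sp": 1.0 - self.fpr}
        )


def roc_and_auc(
    positive_scores: np.ndarray, negative_scores: np.ndarray
) -> RocCurve:
    """ROC over all distinct cutoffs with trapezoidal AROC.

    Tied scores are grouped into single curve points, so mixed-label ties
    appear as diagonal segments, matching the pair-counting statistic
    P(pos > neg) + 0.5 * P(pos = neg).
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    scores = np.concatenate([pos, neg])
    fpr, tpr, thr = _sk_roc_curve(y, scores, drop_intermediate=False)
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, aroc=float(_sk_auc(fpr, tpr)))


def self_consistency(
    training_set: TrainingSet, matrix: SubstitutionMatrix
) -> RocCurve:
    """ROC of benchmark scores with no exclusion (reference = all positives)."""
    pos, neg = self_consistency_scores(training_set, matrix)
    return roc_and_auc(pos, neg)


def loo_roc(training_set: TrainingSet, matrix: SubstitutionMatrix) -> RocCurve:
    """ROC of leave-one-out scores."""
    pos, neg = loo_scores(training_set, matrix)
    return roc_and_auc(pos, neg)


def k_fold_scores(
    training_set: TrainingSet,
    matrix: SubstitutionMatrix,
    k: int,
    rng_seed: int | np.random.Generator = 0,
    sp_target: float = DEFAULT_SP_TARGET,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Pooled k-fold CV scores plus per-fold metrics.

    Positives are partitioned into k random folds (seeded). Held-out
    positives are scored against the retained positives of their fold split;
    each negative is scored against every fold's retained reference and its
    integer similarity sums pooled into a single averaged score. Per-fold
    rows report the fold's AROC and Sn at the working specificity.
    """
    P = len(training_set.positives)
    if not 2 <= k <= P:
        raise ValueError(f"k must be between 2 and the number of positives ({P})")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    perm = rng.permutation(P)
    folds = np.array_split(perm, k)

    spp = np.maximum(
        pairwise_raw_sums(training_set.positive_array, training_set.positive_array, matrix), 0
    ).astype(np.int64)
    snp = np.maximum(
        pairwise_raw_sums(training_set.negative_array, training_set.positive_array, matrix), 0
    ).astype(np.int64)

    pos_scores = np.empty(P, dtype=float)
    neg_numer = np.zeros(snp.shape[0], dtype=np.int64)
    neg_denom = 0
    fold_rows = []
    mask = np.empty(P, dtype=bool)
    for fold_no, fold in enumerate(folds):
        mask[:] = True
        mask[fold] = False
        retained = np.nonzero(mask)[0]
        if retained.size == 0:
            raise ValueError(f"fold {fold_no}: no retained positives")
        held_sums = spp[np.ix_(fold, retained)].sum(axis=1)
        pos_scores[fold] = held_sums / retained.size
        fold_neg_sums = snp[:, retained].sum(axis=1)
        neg_numer += fold_neg_sums
        neg_denom += retained.size
        fold_neg = fold_neg_sums / retained.size
        fold_pos = held_sums / retained.size
        fold_roc = roc_and_auc(fold_pos, fold_neg)
        fold_thr = sn_at_sp(fold_pos, fold_neg, sp_target)
        fold_rows.append(
            {
                "fold": fold_no,
                "n_heldout": fold.size,
                "aroc": fold_roc.aroc,
                "sn": fold_thr.sn,
                "sp": fold_thr.sp,
            }
        )
    neg_scores = neg_numer / neg_denom
    return pos_scores, neg_scores, pd.DataFrame(fold_rows)


def k_fold_cv(
    substrates: Sequence[Substrate],
    sites: Sequence[CleavageSite],
    k: int,
    m: int,
    n: int,
    matrix: SubstitutionMatrix | None = None,
    rng_seed: int | np.random.Generator = 0,
    sp_target: float = DEFAULT_SP_TARGET,
) -> tuple[RocCurve, pd.DataFrame]:
    """k-fold cross-validation of the scorer at a fixed window and matrix."""
    matrix = matrix or SubstitutionMatrix.blosum62()
    ts = build_training_set(substrates, sites, m, n)
    pos, neg, fold_df = k_fold_scores(ts, matrix, k, rng_seed, sp_target)
    return roc_and_auc(pos, neg), fold_df


def metrics_table(
    positive_scores: np.ndarray,
    negative_scores: np.ndarray,
    cutoffs: dict[str, float],
) -> pd.DataFrame:
    """Ac/Sn/Sp/MCC at each named cutoff level (threshold-grid report)."""
    rows = []
    for level, cutoff in cutoffs.items():
        met = confusion_metrics(
            counts_at_cutoff(positive_scores, negative_scores, cutoff)
        )
        rows.append(
            {
                "threshold": level,
                "cutoff": cutoff,
                "ac": met.ac,
                "sn": met.sn,
                "sp": met.sp,
                "mcc": met.mcc,
            }
        )
    return pd.DataFrame(rows)
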