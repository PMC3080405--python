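"""Scikit-learn style estimators wrapping the training pipeline.

:class:`GPSScorer` works at the peptide level (fixed-length windows, binary
labels) and composes with sklearn model selection; :class:`GPSCCD` is the
substrate-level pipeline (window selection, matrix mutation, threshold
calibration, whole-protein scanning).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .dataset import (
    CleavagePeptide,
    CleavageSite,
    Substrate,
    TrainingSet,
    build_training_set,
)
from .evaluation import RocCurve, k_fold_scores, roc_and_auc
from .matrix import SubstitutionMatrix, encode
from .scoring import ScoredSite, predictions_frame, scan_protein, score_windows
from .training import (
    DEFAULT_MAX_STALE,
    DEFAULT_SP_TARGET,
    Model,
    calibrate_thresholds,
    loo_scores,
    mam_optimize,
    mls_select,
)

__all__ = ["GPSScorer", "GPSCCD"]


def _encode_peptides(X) -> np.ndarray:
    if isinstance(X, np.ndarray) and X.dtype == np.uint8 and X.ndim == 2:
        return X
    rows = [
        encode(x.residues if isinstance(x, CleavagePeptide) else str(x)) for x in X
    ]
    lengths = {r.size for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"peptides must share one window length, got {sorted(lengths)}")
    return np.stack(rows)


class GPSScorer(ClassifierMixin, BaseEstimator):
    """Average-similarity peptide classifier at a fixed window shape.

    ``fit`` stores the positive peptides as the reference set, optionally
    hill-climbs the substitution matrix (matrix mutation) against the
    negatives, and calibrates high/medium/low cutoffs on leave-one-out
    scores. ``decision_function`` returns the mean clamped BLOSUM-style
    similarity to the reference set; ``predict`` thresholds it at the
    configured level.

    Parameters
    ----------
    window : (m, n) or None
        Upstream/downstream residue counts; inferred bookkeeping only — the
        peptides themselves fix the total length.
    matrix : SubstitutionMatrix or None
        Initial matrix (default BLOSUM62 with zeroed ``*`` scores).
    mam : bool
        Run matrix-mutation hill climbing during fit.
    sp_target : float
        Working specificity for sensitivity optimization.
    threshold_sp : mapping level -> specificity for cutoff calibration.
    level : threshold level used by ``predict``.
    max_stale : consecutive rejected mutations ending the climb.
    random_state : seed for the mutation proposals.
    """

    def __init__(
        self,
        window: tuple[int, int] | None = None,
        matrix: SubstitutionMatrix | None = None,
        mam: bool = True,
        sp_target: float = DEFAULT_SP_TARGET,
        threshold_sp: dict[str, float] | None = None,
        level: str = "medium",
        max_stale: int = DEFAULT_MAX_STALE,
        random_state: int | None = 0,
    ):
        self.window = window
        self.matrix = matrix
        self.mam = mam
        self.sp_target = sp_target
        self.threshold_sp = threshold_sp
        self.level = level
        self.max_stale = max_stale
        self.random_state = random_state

    def _training_set(self, X, y, origins) -> TrainingSet:
        Xe = _encode_peptides(X)
        y = np.asarray(y)
        if y.shape[0] != Xe.shape[0]:
            raise ValueError("X and y length mismatch")
        if set(np.unique(y)) - {0, 1}:
            raise ValueError("y must be binary (1 = verified cleavage site)")
        L = Xe.shape[1]
        if self.window is not None:
            m, n = self.window
            if m + n != L:
                raise ValueError(f"window {self.window} inconsistent with length {L}")
        else:
            m, n = L - L // 2, L // 2
        from .matrix import decode

        def peps(mask):
            out = []
            for i in np.nonzero(mask)[0]:
                org = tuple(origins[i]) if origins is not None else ("peptide", int(i))
                out.append(CleavagePeptide(decode(Xe[i]), m, n, origin=org))
            return out

        return TrainingSet(
            positives=peps(y == 1), negatives=peps(y == 0), m=m, n=n
        )

    def fit(self, X, y, origins: Sequence[tuple[str, int]] | None = None):
        """Fit from peptide windows ``X`` and binary labels ``y``.

        ``origins`` optionally carries (substrate, position) provenance used
        for leave-one-out exclusion; defaults to peptide identity.
        """
        ts = self._training_set(X, y, origins)
        if len(ts.positives) < 2:
            raise ValueError("need at least 2 positive peptides")
        matrix0 = self.matrix or SubstitutionMatrix.blosum62()
        if self.mam:
            matrix, trace = mam_optimize(
                ts,
                matrix0,
                self.sp_target,
                rng_seed=self.random_state or 0,
                max_stale=self.max_stale,
            )
            self.mam_trace_ = trace
        else:
            matrix = matrix0
            self.mam_trace_ = pd.DataFrame(
                columns=["proposal", "a", "b", "delta", "sn_before", "sn_after"]
            )
        self.matrix_ = matrix
        self.training_set_ = ts
        self.positives_ = ts.positives
        pos_scores, neg_scores = loo_scores(ts, matrix)
        self.loo_positive_scores_ = pos_scores
        self.loo_negative_scores_ = neg_scores
        self.cutoffs_ = calibrate_thresholds(
            pos_scores, neg_scores, self.threshold_sp
        )
        self.classes_ = np.array([0, 1])
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "matrix_")
        Xe = _encode_peptides(X)
        return score_windows(Xe, self.training_set_.positive_array, self.matrix_)

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cutoffs_")
        if self.level not in self.cutoffs_:
            raise ValueError(f"unknown threshold level {self.level!r}")
        return (self.decision_function(X) >= self.cutoffs_[self.level]).astype(int)

    def loo_roc_(self) -> RocCurve:
        check_is_fitted(self, "loo_positive_scores_")
        return roc_and_auc(self.loo_positive_scores_, self.loo_negative_scores_)


class GPSCCD(BaseEstimator):
    """Full cleavage-site predictor over substrates and a site table.

    ``fit`` runs motif-length selection over the (m, n) grid under BLOSUM62,
    rebuilds the training set at the chosen window, optionally runs matrix
    mutation, and calibrates the three threshold cutoffs on final
    leave-one-out scores. ``scan``/``predict`` slide the trained scorer over
    every bond of a substrate.
    """

    def __init__(
        self,
        m_grid: Sequence[int] | range = range(1, 31),
        n_grid: Sequence[int] | range = range(1, 31),
        sp_target: float = DEFAULT_SP_TARGET,
        threshold_sp: dict[str, float] | None = None,
        mam: bool = True,
        max_stale: int = DEFAULT_MAX_STALE,
        level: str = "high",
        random_state: int | None = 0,
    ):
        self.m_grid = m_grid
        self.n_grid = n_grid
        self.sp_target = sp_target
        self.threshold_sp = threshold_sp
        self.mam = mam
        self.max_stale = max_stale
        self.level = level
        self.random_state = random_state

    def fit(self, substrates: Sequence[Substrate], sites: Sequence[CleavageSite]):
        matrix0 = SubstitutionMatrix.blosum62()
        mls = mls_select(
            substrates, sites, self.m_grid, self.n_grid, self.sp_target, matrix0
        )
        self.m_, self.n_ = mls.m, mls.n
        self.grid_report_ = mls.report
        ts = build_training_set(substrates, sites, mls.m, mls.n)
        self.training_set_ = ts
        if self.mam:
            matrix, trace = mam_optimize(
                ts,
                matrix0,
                self.sp_target,
                rng_seed=self.random_state or 0,
                max_stale=self.max_stale,
            )
            self.mam_trace_ = trace
            label = "GPS-2.0-style"
        else:
            matrix, label = matrix0, "GPS-1.1-style"
            self.mam_trace_ = pd.DataFrame(
                columns=["proposal", "a", "b", "delta", "sn_before", "sn_after"]
            )
        self.matrix_ = matrix
        pos_scores, neg_scores = loo_scores(ts, matrix)
        self.loo_positive_scores_ = pos_scores
        self.loo_negative_scores_ = neg_scores
        self.cutoffs_ = calibrate_thresholds(pos_scores, neg_scores, self.threshold_sp)
        log = {"grid_report": mls.report}
        if self.mam:
            log["mam_trace"] = self.mam_trace_
        self.model_ = Model(
            m=mls.m,
            n=mls.n,
            matrix=matrix,
            positives=ts.positives,
            cutoffs=self.cutoffs_,
            sp_target=self.sp_target,
            seed=self.random_state,
            label=label,
            training_log=log,
        )
        return self

    def scan(self, substrate: Substrate) -> list[ScoredSite]:
        """Score every bond of one substrate; threshold calls attached."""
        check_is_fitted(self, "model_")
        return scan_protein(substrate, self.model_)

    def predict(
        self, substrates: Sequence[Substrate], level: str | None = None
    ) -> pd.DataFrame:
        """Scan substrates; keep bonds meeting ``level`` ('all' keeps every bond)."""
        check_is_fitted(self, "model_")
        level = level or self.level
        frames = [predictions_frame(self.scan(s)) for s in substrates]
        df = pd.concat(frames, ignore_index=True) if frames else predictions_frame([])
        if level != "all":
            if level not in self.cutoffs_:
                raise ValueError(f"unknown threshold level {level!r}")
            df = df[df.score >= self.cutoffs_[level]].reset_index(drop=True)
        return df

    def loo_roc_(self) -> RocCurve:
        check_is_fitted(self, "loo_positive_scores_")
        return roc_and_auc(self.loo_positive_scores_, self.loo_negative_scores_)

    def cross_validate(self, k: int, rng_seed: int | None = None):
        """k-fold CV of the fitted window/matrix; returns (RocCurve, fold table)."""
        check_is_fitted(self, "model_")
        seed = self.random_state or 0 if rng_seed is None else rng_seed
        pos, neg, folds = k_fold_scores(
            self.training_set_, self.matrix_, k, seed, self.sp_target
        )
        return roc_and_auc(pos, neg), folds
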