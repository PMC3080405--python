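"""Model training: motif-length selection, matrix mutation, threshold calibration.

Training runs in a fixed order. First, motif-length selection (MLS)
exhaustively scans window shapes (m, n), scoring each by leave-one-out (LOO)
sensitivity at a fixed specificity (default 90%) under the initial BLOSUM62
matrix. Second, matrix mutation (MaM) hill-climbs the substitution matrix at
the selected window: single entries are nudged by +/-1 at random and a
mutation is kept only if LOO sensitivity at the fixed specificity strictly
increases. Finally three score cutoffs (high/medium/low) are calibrated on
the final LOO score distributions at specificity levels 95/90/85%. The order
MLS-then-MaM is load-bearing: the window is chosen under the un-mutated
matrix.

All pairwise similarities are integers; LOO machinery accumulates integer
sums and divides once so that evaluation is exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .dataset import (
    CleavagePeptide,
    CleavageSite,
    Substrate,
    TrainingSet,
    build_training_set,
)
from .matrix import AMINO_ACIDS, SubstitutionMatrix, encode
from .scoring import pairwise_raw_sums

DEFAULT_SP_TARGET = 0.90
DEFAULT_THRESHOLD_SP = {"high": 0.95, "medium": 0.90, "low": 0.85}
DEFAULT_MAX_STALE = 2000
MODEL_SCHEMA = "gpsccd-model/1"


class ThresholdResult(NamedTuple):
    """Sensitivity and score cutoff achieving at least the target specificity."""

    sn: float
    cutoff: float
    sp: float


def sn_at_sp(
    positive_scores: np.ndarray,
    negative_scores: np.ndarray,
    sp_target: float,
) -> ThresholdResult:
    """Smallest observed cutoff whose specificity reaches ``sp_target``.

    A bond is called positive at ``score >= cutoff``; specificity is the
    fraction of negatives strictly below the cutoff. The cutoff is the
    smallest observed score achieving Sp >= target; if no observed score
    does, a sentinel just above the maximum is used (Sn = 0, Sp = 1).
    """
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be non-empty")
    if not 0.0 < sp_target < 1.0:
        raise ValueError(f"sp_target must be in (0, 1), got {sp_target}")
    neg_sorted = np.sort(neg)
    k = int(math.ceil(sp_target * neg.size - 1e-9))  # negatives required below cutoff
    values = np.unique(np.concatenate([pos, neg]))
    if k == 0:
        cutoff = float(values[0])
    else:
        bar = neg_sorted[k - 1]
        idx = np.searchsorted(values, bar, side="right")
        cutoff = float(values[idx]) if idx < values.size else float(values[-1] + 1.0)
    sn = float(np.mean(pos >= cutoff))
    sp = float(np.mean(neg < cutoff))
    return ThresholdResult(sn=sn, cutoff=cutoff, sp=sp)


# ---------------------------------------------------------------------------
# Leave-one-out scoring (integer accumulation)
# ---------------------------------------------------------------------------


def loo_sums(
    pos_idx: np.ndarray,
    neg_idx: np.ndarray,
    matrix: SubstitutionMatrix | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Integer clamped-similarity sums for LOO evaluation.

    Returns (pos_sums, neg_sums): each positive's sum over the other
    positives (self excluded), and each negative's sum over all positives.
    """
    spp = np.maximum(pairwise_raw_sums(pos_idx, pos_idx, matrix), 0)
    pos_sums = spp.sum(axis=1, dtype=np.int64) - np.diagonal(spp).astype(np.int64)
    snp = np.maximum(pairwise_raw_sums(neg_idx, pos_idx, matrix), 0)
    neg_sums = snp.sum(axis=1, dtype=np.int64)
    return pos_sums, neg_sums


def loo_scores(
    training_set: TrainingSet,
    matrix: SubstitutionMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """LOO prediction scores: positives scored with themselves removed from
    the reference set, negatives against all positives."""
    P = len(training_set.positives)
    if P < 2:
        raise ValueError("leave-one-out requires at least 2 positive peptides")
    pos_sums, neg_sums = loo_sums(
        training_set.positive_array, training_set.negative_array, matrix
    )
    return pos_sums / (P - 1), neg_sums / P


def self_consistency_scores(
    training_set: TrainingSet,
    matrix: SubstitutionMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Scores with no exclusion: every peptide compared to all positives,
    training positives included (each positive therefore meets itself)."""
    P = len(training_set.positives)
    if P < 1:
        raise ValueError("need at least 1 positive peptide")
    spp = np.maximum(
        pairwise_raw_sums(training_set.positive_array, training_set.positive_array, matrix), 0
    )
    snp = np.maximum(
        pairwise_raw_sums(training_set.negative_array, training_set.positive_array, matrix), 0
    )
    return (
        spp.sum(axis=1, dtype=np.int64) / P,
        snp.sum(axis=1, dtype=np.int64) / P,
    )


# ---------------------------------------------------------------------------
# Motif length selection
# ---------------------------------------------------------------------------


class MLSResult(NamedTuple):
    m: int
    n: int
    report: pd.DataFrame


def _grid_cell_sums(
    rows: np.ndarray,
    pos_full: np.ndarray,
    matrix_table: np.ndarray,
    cells: list[tuple[int, int]],
    m_max: int,
    exclude_diag_offset: int | None,
) -> np.ndarray:
    """Clamped-similarity sums of ``rows`` vs positives for every (m, n) cell.

    Window (m, n) occupies columns [m_max-m, m_max+n) of the full windows, so
    a single cumulative sum over positions serves every cell. Returns int64
    (len(cells), len(rows)); with ``exclude_diag_offset`` set, pair
    (i, i+offset) is removed from row i's sum (LOO self-exclusion).
    """
    out = np.zeros((len(cells), rows.shape[0]), dtype=np.int64)
    P = pos_full.shape[0]
    chunk = max(1, int(3.0e7 / max(1, P * pos_full.shape[1])))
    for start in range(0, rows.shape[0], chunk):
        block = rows[start : start + chunk]
        per_pos = matrix_table[block[:, None, :], pos_full[None, :, :]].astype(
            np.int32, copy=False
        )
        np.cumsum(per_pos, axis=2, out=per_pos)
        for ci, (m, n) in enumerate(cells):
            hi = per_pos[:, :, m_max + n - 1]
            raw = hi if m == m_max else hi - per_pos[:, :, m_max - m - 1]
            clamped = np.maximum(raw, 0)
            sums = clamped.sum(axis=1, dtype=np.int64)
            if exclude_diag_offset is not None:
                rng_idx = np.arange(start, start + block.shape[0])
                sums -= clamped[np.arange(block.shape[0]), rng_idx].astype(np.int64)
            out[ci, start : start + block.shape[0]] = sums
    return out


def mls_select(
    substrates: Sequence[Substrate],
    sites: Sequence[CleavageSite],
    m_grid: Sequence[int] | range = range(1, 31),
    n_grid: Sequence[int] | range = range(1, 31),
    sp_target: float = DEFAULT_SP_TARGET,
    matrix: SubstitutionMatrix | None = None,
) -> MLSResult:
    """Exhaustive window-shape search maximizing LOO Sn at fixed Sp.

    Every combination of m upstream and n downstream residues is evaluated by
    leave-one-out under ``matrix`` (default BLOSUM62); ties break toward the
    more compact window (smaller m+n, then smaller m). The report holds one
    row per cell with its Sn, cutoff and achieved Sp.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    m_grid = sorted(set(int(m) for m in m_grid))
    n_grid = sorted(set(int(n) for n in n_grid))
    if not m_grid or not n_grid or m_grid[0] < 1 or n_grid[0] < 1:
        raise ValueError("m_grid and n_grid must contain integers >= 1")
    m_max, n_max = m_grid[-1], n_grid[-1]
    ts = build_training_set(substrates, sites, m_max, n_max)
    P = len(ts.positives)
    if P < 2:
        raise ValueError("motif-length selection requires at least 2 positive sites")
    pos_full = ts.positive_array
    neg_full = ts.negative_array
    cells = [(m, n) for m in m_grid for n in n_grid]
    table = matrix.array
    pos_cell_sums = _grid_cell_sums(pos_full, pos_full, table, cells, m_max, 0)
    neg_cell_sums = _grid_cell_sums(neg_full, pos_full, table, cells, m_max, None)

    records = []
    for ci, (m, n) in enumerate(cells):
        res = sn_at_sp(pos_cell_sums[ci] / (P - 1), neg_cell_sums[ci] / P, sp_target)
        records.append((m, n, res.sn, res.cutoff, res.sp))
    report = pd.DataFrame(records, columns=["m", "n", "sn", "cutoff", "sp"])
    # highest Sn; ties prefer the compact window (smaller m+n, then smaller m)
    order = report.assign(span=report.m + report.n).sort_values(
        by=["sn", "span", "m"], ascending=[False, True, True], kind="mergesort"
    )
    best = order.iloc[0]
    return MLSResult(m=int(best.m), n=int(best.n), report=report)


# ---------------------------------------------------------------------------
# Matrix mutation (MaM)
# ---------------------------------------------------------------------------


def _loo_sn_from_raw(
    raw_pp: np.ndarray, raw_np: np.ndarray, sp_target: float
) -> ThresholdResult:
    P = raw_pp.shape[0]
    cpp = np.maximum(raw_pp, 0)
    pos_sums = cpp.sum(axis=1, dtype=np.int64) - np.diagonal(cpp).astype(np.int64)
    neg_sums = np.maximum(raw_np, 0).sum(axis=1, dtype=np.int64)
    return sn_at_sp(pos_sums / (P - 1), neg_sums / P, sp_target)


def mam_optimize(
    training_set: TrainingSet,
    matrix0: SubstitutionMatrix | None = None,
    sp_target: float = DEFAULT_SP_TARGET,
    rng_seed: int | np.random.Generator = 0,
    max_stale: int = DEFAULT_MAX_STALE,
) -> tuple[SubstitutionMatrix, pd.DataFrame]:
    """Hill-climb the substitution matrix by random +/-1 entry mutations.

    Each proposal picks a uniformly random ordered amino-acid pair (``*`` is
    frozen) and a random sign; the mutation is adopted only if LOO Sn at
    ``sp_target`` strictly increases. The climb stops after ``max_stale``
    consecutive rejections (or immediately once Sn reaches 1.0, where no
    strict improvement is possible). Sensitivity after each proposal is
    evaluated incrementally: a +/-1 change to entry (a, b) shifts each raw
    pairwise sum by the count of window positions where the candidate shows
    ``a`` against a reference ``b`` — equivalent to full recomputation.

    Returns the final matrix and the accepted-step trace.
    """
    if max_stale < 1:
        raise ValueError("max_stale must be >= 1")
    matrix0 = matrix0 or SubstitutionMatrix.blosum62()
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    pos_idx = training_set.positive_array
    neg_idx = training_set.negative_array
    P = pos_idx.shape[0]
    if P < 2:
        raise ValueError("matrix mutation requires at least 2 positive peptides")

    table = matrix0.array.copy()
    raw_pp = pairwise_raw_sums(pos_idx, pos_idx, table)
    raw_np = pairwise_raw_sums(neg_idx, pos_idx, table)
    current = _loo_sn_from_raw(raw_pp, raw_np, sp_target)

    trace_rows: list[dict] = []
    n_aa = len(AMINO_ACIDS)
    stale = 0
    proposal_no = 0
    while stale < max_stale and current.sn < 1.0:
        a = int(rng.integers(n_aa))
        b = int(rng.integers(n_aa))
        delta = 1 if int(rng.integers(2)) == 0 else -1
        proposal_no += 1

        pos_b = (pos_idx == b).astype(np.float32)
        cnt_pp = ((pos_idx == a).astype(np.float32) @ pos_b.T).astype(np.int32)
        cnt_np = ((neg_idx == a).astype(np.float32) @ pos_b.T).astype(np.int32)
        cand_pp = raw_pp + delta * cnt_pp
        cand_np = raw_np + delta * cnt_np
        cand = _loo_sn_from_raw(cand_pp, cand_np, sp_target)
        if cand.sn > current.sn:
            trace_rows.append(
                {
                    "proposal": proposal_no,
                    "a": AMINO_ACIDS[a],
                    "b": AMINO_ACIDS[b],
                    "delta": delta,
                    "sn_before": current.sn,
                    "sn_after": cand.sn,
                }
            )
            table[a, b] += delta
            raw_pp, raw_np = cand_pp, cand_np
            current = cand
            stale = 0
        else:
            stale += 1

    trace = pd.DataFrame(
        trace_rows, columns=["proposal", "a", "b", "delta", "sn_before", "sn_after"]
    )
    label = matrix0.label + "+MaM" if trace_rows else matrix0.label
    return SubstitutionMatrix(table, label=label), trace


# ---------------------------------------------------------------------------
# Threshold calibration and the trained model
# ---------------------------------------------------------------------------


def calibrate_thresholds(
    positive_scores: np.ndarray,
    negative_scores: np.ndarray,
    sp_levels: dict[str, float] | None = None,
) -> dict[str, float]:
    """Score cutoffs at the high/medium/low specificity levels (95/90/85%).

    Computed on the LOO score distributions of the final matrix; higher Sp
    targets yield higher cutoffs, so high >= medium >= low by construction.
    """
    sp_levels = sp_levels or DEFAULT_THRESHOLD_SP
    return {
        level: sn_at_sp(positive_scores, negative_scores, sp).cutoff
        for level, sp in sp_levels.items()
    }


@dataclass
class Model:
    """Trained artifact: window shape, matrix, reference peptides, cutoffs."""

    m: int
    n: int
    matrix: SubstitutionMatrix
    positives: list[CleavagePeptide]
    cutoffs: dict[str, float]
    sp_target: float = DEFAULT_SP_TARGET
    seed: int | None = None
    label: str = "GPS-2.0-style"
    training_log: dict = field(default_factory=dict)
    _pos_idx: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def positive_array(self) -> np.ndarray:
        if self._pos_idx is None:
            self._pos_idx = np.stack([encode(p.residues) for p in self.positives])
        return self._pos_idx

    def save(self, directory: str | Path) -> None:
        """Write model.json + matrix.tsv + positives.tsv (+ training logs)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.matrix.to_tsv(directory / "matrix.tsv")
        pd.DataFrame(
            [
                {"substrate": p.origin[0] if p.origin else "",
                 "p1": p.origin[1] if p.origin else -1,
                 "peptide": p.residues}
                for p in self.positives
            ]
        ).to_csv(directory / "positives.tsv", sep="\t", index=False)
        meta = {
            "schema": MODEL_SCHEMA,
            "label": self.label,
            "m": self.m,
            "n": self.n,
            "sp_target": self.sp_target,
            "seed": self.seed,
            "cutoffs": {k: self.cutoffs[k] for k in sorted(self.cutoffs)},
            "matrix_file": "matrix.tsv",
            "positives_file": "positives.tsv",
            "matrix_label": self.matrix.label,
        }
        (directory / "model.json").write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
        for name, obj in self.training_log.items():
            if isinstance(obj, pd.DataFrame):
                obj.to_csv(directory / f"{name}.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "Model":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        if meta.get("schema") != MODEL_SCHEMA:
            raise ValueError(f"unrecognized model schema {meta.get('schema')!r}")
        matrix = SubstitutionMatrix.from_tsv(
            directory / meta["matrix_file"], label=meta.get("matrix_label", "")
        )
        pos_df = pd.read_csv(directory / meta["positives_file"], sep="\t")
        m, n = int(meta["m"]), int(meta["n"])
        positives = [
            CleavagePeptide(
                residues=row.peptide,
                m=m,
                n=n,
                origin=(str(row.substrate), int(row.p1)) if row.p1 != -1 else None,
            )
            for row in pos_df.itertuples()
        ]
        return cls(
            m=m,
            n=n,
            matrix=matrix,
            positives=positives,
            cutoffs={k: float(v) for k, v in meta["cutoffs"].items()},
            sp_target=float(meta["sp_target"]),
            seed=meta.get("seed"),
            label=meta.get("label", ""),
        )


def train_model(
    substrates: Sequence[Substrate],
    sites: Sequence[CleavageSite],
    m_grid: Sequence[int] | range = range(1, 31),
    n_grid: Sequence[int] | range = range(1, 31),
    sp_target: float = DEFAULT_SP_TARGET,
    threshold_sp: dict[str, float] | None = None,
    mam: bool = True,
    max_stale: int = DEFAULT_MAX_STALE,
    random_state: int | None = 0,
) -> Model:
    """Full training pipeline: MLS -> rebuild at (m, n) -> MaM -> calibration.

    With ``mam=False`` the matrix stays at BLOSUM62, reproducing the
    un-mutated (GPS 1.1-style) variant of the scorer.
    """
    matrix0 = SubstitutionMatrix.blosum62()
    mls = mls_select(substrates, sites, m_grid, n_grid, sp_target, matrix0)
    ts = build_training_set(substrates, sites, mls.m, mls.n)
    log: dict = {"grid_report": mls.report}
    if mam:
        matrix, trace = mam_optimize(
            ts, matrix0, sp_target, rng_seed=random_state or 0, max_stale=max_stale
        )
        log["mam_trace"] = trace
        label = "GPS-2.0-style"
    else:
        matrix = matrix0
        label = "GPS-1.1-style"
    pos_scores, neg_scores = loo_scores(ts, matrix)
    cutoffs = calibrate_thresholds(pos_scores, neg_scores, threshold_sp)
    return Model(
        m=mls.m,
        n=mls.n,
        matrix=matrix,
        positives=ts.positives,
        cutoffs=cutoffs,
        sp_target=sp_target,
        seed=random_state,
        label=label,
        training_log=log,
    )
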