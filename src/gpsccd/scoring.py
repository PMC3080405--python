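"""Group-based similarity scoring of cleavage peptides.

The similarity of two same-shape windows A and B is the position-wise sum of
substitution scores, clamped at zero:

    S(A, B) = max(0, sum_i Score(A_i, B_i))

A candidate window's prediction score is the mean of S(candidate, p) over all
experimentally verified (positive) peptides p. Because every pairwise S is an
integer, sums are accumulated as integers and divided once, which keeps the
scorer exactly reproducible across equivalent evaluation orders.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import CleavagePeptide, Substrate, encode_substrate_windows
from .matrix import SubstitutionMatrix, encode

if TYPE_CHECKING:  # pragma: no cover
    from .training import Model

THRESHOLD_LEVELS = ("high", "medium", "low")


@dataclass(frozen=True)
class ScoredSite:
    """One scanned bond: position, window, score, and the threshold levels met."""

    substrate_id: str
    p1: int
    peptide: CleavagePeptide
    score: float
    calls: frozenset[str] = field(default_factory=frozenset)

    @property
    def best_call(self) -> str | None:
        for level in THRESHOLD_LEVELS:
            if level in self.calls:
                return level
        return None


def _as_indices(peptide: CleavagePeptide | str | np.ndarray) -> np.ndarray:
    if isinstance(peptide, CleavagePeptide):
        return encode(peptide.residues)
    if isinstance(peptide, str):
        return encode(peptide)
    return np.asarray(peptide, dtype=np.uint8)


def pairwise_raw_sums(
    a: np.ndarray,
    b: np.ndarray,
    matrix: SubstitutionMatrix | np.ndarray,
    chunk: int = 2048,
) -> np.ndarray:
    """Unclamped position-wise score sums for every (row of a, row of b) pair.

    ``a`` (A, L) and ``b`` (B, L) are encoded windows; result is int32 (A, B).
    Chunked over ``a`` to bound the (chunk, B, L) gather buffer.
    """
    table = matrix.array if isinstance(matrix, SubstitutionMatrix) else np.asarray(matrix)
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    if a.shape[1] != b.shape[1]:
        raise ValueError(
            f"window length mismatch: {a.shape[1]} vs {b.shape[1]}"
        )
    out = np.empty((a.shape[0], b.shape[0]), dtype=np.int32)
    for start in range(0, a.shape[0], chunk):
        block = a[start : start + chunk]
        out[start : start + chunk] = table[block[:, None, :], b[None, :, :]].sum(
            axis=2, dtype=np.int32
        )
    return out


def pairwise_similarities(
    a: np.ndarray, b: np.ndarray, matrix: SubstitutionMatrix | np.ndarray, chunk: int = 2048
) -> np.ndarray:
    """Clamped similarities max(0, S_raw) for every pair; int32 (A, B)."""
    raw = pairwise_raw_sums(a, b, matrix, chunk=chunk)
    np.maximum(raw, 0, out=raw)
    return raw


def peptide_similarity(
    a: CleavagePeptide | str,
    b: CleavagePeptide | str,
    matrix: SubstitutionMatrix,
) -> int:
    """S(A, B): clamped position-wise substitution-score sum of two windows."""
    if isinstance(a, CleavagePeptide) and isinstance(b, CleavagePeptide):
        if (a.m, a.n) != (b.m, b.n):
            raise ValueError(
                f"window shape mismatch: ({a.m},{a.n}) vs ({b.m},{b.n})"
            )
    ia, ib = _as_indices(a), _as_indices(b)
    return int(pairwise_similarities(ia[None, :], ib[None, :], matrix)[0, 0])


def prediction_score(
    candidate: CleavagePeptide | str,
    positives: Sequence[CleavagePeptide],
    matrix: SubstitutionMatrix,
    exclude_origin: tuple[str, int] | None = None,
) -> float:
    """Mean clamped similarity of ``candidate`` to the verified peptides.

    ``exclude_origin`` drops reference peptides from that bond (leave-one-out
    and self-score suppression).
    """
    retained = [
        p for p in positives if exclude_origin is None or p.origin != exclude_origin
    ]
    if not retained:
        raise ValueError("no reference peptides retained after exclusion")
    cand = _as_indices(candidate)[None, :]
    refs = np.stack([_as_indices(p) for p in retained])
    sims = pairwise_similarities(cand, refs, matrix)
    return float(sims.sum(dtype=np.int64) / len(retained))


def score_windows(
    windows: np.ndarray,
    positive_windows: np.ndarray,
    matrix: SubstitutionMatrix | np.ndarray,
    chunk: int = 2048,
) -> np.ndarray:
    """Prediction score for each encoded window row against the positive set."""
    sims = pairwise_similarities(windows, positive_windows, matrix, chunk=chunk)
    return sims.sum(axis=1, dtype=np.int64) / positive_windows.shape[0]


def assign_calls(score: float, cutoffs: dict[str, float]) -> frozenset[str]:
    """Threshold labels met by ``score`` (high implies medium implies low)."""
    return frozenset(level for level, cut in cutoffs.items() if score >= cut)


def scan_protein(substrate: Substrate, model: "Model") -> list[ScoredSite]:
    """Score every bond 1..L-1 of a substrate with a trained model."""
    from .dataset import extract_peptide  # local import to keep module deps acyclic

    windows = encode_substrate_windows(substrate.sequence, model.m, model.n)
    scores = score_windows(windows, model.positive_array, model.matrix)
    sites = []
    for p1, score in enumerate(scores, start=1):
        pep = extract_peptide(substrate.sequence, p1, model.m, model.n)
        pep = CleavagePeptide(pep.residues, model.m, model.n, origin=(substrate.id, p1))
        sites.append(
            ScoredSite(
                substrate_id=substrate.id,
                p1=p1,
                peptide=pep,
                score=float(score),
                calls=assign_calls(float(score), model.cutoffs),
            )
        )
    return sites


def predictions_frame(scored: Iterable[ScoredSite]) -> pd.DataFrame:
    """Tabular view of scanner output (peptide shown with '|' at the bond)."""
    rows = [
        {
            "substrate": s.substrate_id,
            "position": s.p1,
            "p1_residue": s.peptide.residues[s.peptide.m - 1],
            "peptide": str(s.peptide),
            "score": s.score,
            "call": s.best_call or "",
        }
        for s in scored
    ]
    return pd.DataFrame(
        rows, columns=["substrate", "position", "p1_residue", "peptide", "score", "call"]
    )


def write_predictions_tsv(
    scored: Iterable[ScoredSite], path: str | Path, header_lines: Sequence[str] = ()
) -> None:
    df = predictions_frame(scored)
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
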